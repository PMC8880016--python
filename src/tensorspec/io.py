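"""Data model and file I/O for labeled absorbance spectra.

A :class:`SpectrumSet` is the pipeline's currency: a uniform descending
wavenumber grid plus an ``n_samples x n_points`` absorbance matrix and a
class label per sample. Spectra are stored in spectrometer order (high to
low cm^-1); files supplied in ascending order are reversed on read.

Supported formats are delimited text (CSV/TSV, one sample per row with a
header row of wavenumbers and an optional ``label`` column, or one sample
per column with the first column holding wavenumbers) and a minimal
JCAMP-DX-style single-spectrum format (``##XYDATA=(X++(Y..Y))``).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    FormatError,
    LabelingError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WavenumberGrid",
    "SpectrumSet",
    "make_grid",
    "read_spectra",
    "write_spectra",
    "read_jcampdx",
    "write_jcampdx",
    "read_jcampdx_many",
]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly decreasing wavenumber grid.

    Point ``i`` sits at ``nu_max - i * resolution`` for
    ``i = 0 .. n_points - 1`` (half-open convention: ``nu_min`` itself is
    not a grid point, so a 12,500-4,000 cm^-1 range at 4 cm^-1 holds
    exactly (12500 - 4000) / 4 = 2125 points).

    Parameters
    ----------
    nu_max : float
        First (highest) grid point, cm^-1.
    resolution : float
        Spacing between adjacent points, cm^-1 (positive; the grid
        descends).
    n_points : int
        Number of grid points.
    """

    nu_max: float
    resolution: float
    n_points: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ConfigError(f"resolution must be positive, got {self.resolution}")
        if self.n_points < 1:
            raise ConfigError(f"grid needs at least one point, got {self.n_points}")
        if self.nu_max <= 0:
            raise ConfigError(f"nu_max must be positive, got {self.nu_max}")

    @property
    def nu_min(self) -> float:
        """Lower edge of the half-open range (not itself a grid point)."""
        return self.nu_max - self.resolution * self.n_points

    @property
    def values(self) -> np.ndarray:
        """Grid points, strictly decreasing, cm^-1."""
        return self.nu_max - self.resolution * np.arange(self.n_points)

    @classmethod
    def from_range(cls, nu_max: float, nu_min: float, resolution: float) -> "WavenumberGrid":
        if resolution <= 0:
            raise ConfigError(f"resolution must be positive, got {resolution}")
        if not nu_max > nu_min > 0:
            raise ConfigError(f"need nu_max > nu_min > 0, got {nu_max}, {nu_min}")
        n = int(round((nu_max - nu_min) / resolution))
        if n < 1:
            raise ConfigError("empty grid range")
        return cls(nu_max=float(nu_max), resolution=float(resolution), n_points=n)

    @classmethod
    def from_values(cls, values: np.ndarray, rtol: float = 1e-6) -> "WavenumberGrid":
        """Build a grid from an explicit descending array of points."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise FormatError("grid values must be a non-empty 1-D array")
        if values.size == 1:
            return cls(nu_max=float(values[0]), resolution=1.0, n_points=1)
        steps = -np.diff(values)
        step = steps.mean()
        if step <= 0 or np.any(np.abs(steps - step) > rtol * abs(step) + 1e-9):
            raise FormatError("wavenumber grid is not uniform and descending")
        return cls(nu_max=float(values[0]), resolution=float(step), n_points=values.size)

    def slice(self, start: int, stop: int) -> "WavenumberGrid":
        """Contiguous index-range sub-grid (``start`` inclusive, ``stop`` exclusive)."""
        if not (0 <= start < stop <= self.n_points):
            raise ConfigError(f"invalid grid slice [{start}:{stop}]")
        return WavenumberGrid(
            nu_max=self.nu_max - self.resolution * start,
            resolution=self.resolution,
            n_points=stop - start,
        )

    def isclose(self, other: "WavenumberGrid", atol: float = 1e-9) -> bool:
        return (
            self.n_points == other.n_points
            and abs(self.nu_max - other.nu_max) <= atol
            and abs(self.resolution - other.resolution) <= atol
        )


def make_grid(nu_max: float, nu_min: float, resolution: float) -> WavenumberGrid:
    """Construct a grid over ``[nu_min, nu_max)`` at the given resolution.

    ``make_grid(12500, 4000, 4)`` yields 2125 points running 12500 down
    to 4004 cm^-1.
    """
    return WavenumberGrid.from_range(nu_max, nu_min, resolution)


@dataclass
class SpectrumSet:
    """Labeled absorbance spectra on a common wavenumber grid.

    Attributes
    ----------
    grid : WavenumberGrid
        Shared descending grid.
    absorbance : ndarray, shape (n_samples, n_points)
        Absorbance (or exported transmittance-mode) values.
    labels : ndarray of str, shape (n_samples,)
        Class label per sample (e.g. grades "I".."V").
    sample_ids : list of str
        Opaque per-sample identifiers.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.absorbance.shape[1] != self.grid.n_points:
            raise FormatError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has "
                f"{self.grid.n_points} points"
            )
        if self.labels.shape[0] != self.absorbance.shape[0]:
            raise LabelingError(
                f"{self.absorbance.shape[0]} samples but {self.labels.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ParseError("absorbance contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise LabelingError("sample_ids length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    @property
    def classes(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def replace(self, *, grid=None, absorbance=None) -> "SpectrumSet":
        """Copy with a new grid/absorbance, keeping labels and ids."""
        return SpectrumSet(
            grid=grid if grid is not None else self.grid,
            absorbance=absorbance if absorbance is not None else self.absorbance.copy(),
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )

    def isclose(self, other: "SpectrumSet", atol: float = 1e-12) -> bool:
        # grids compare by their point values: a single-point grid read
        # back from a file cannot recover its nominal resolution
        return (
            self.grid.n_points == other.grid.n_points
            and bool(np.allclose(self.grid.values, other.grid.values, atol=max(atol, 1e-9)))
            and self.absorbance.shape == other.absorbance.shape
            and bool(np.all(np.abs(self.absorbance - other.absorbance) <= atol))
            and list(self.labels) == list(other.labels)
        )


_FLOAT_FMT = "%.17g"


def _sniff_delimiter(first_line: str) -> str:
    try:
        return csv.Sniffer().sniff(first_line, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _load_sidecar_labels(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise LabelingError(f"sidecar {path} needs sample_id and label columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_spectra(
    path: str | Path,
    layout: str = "samples_as_rows",
    label_source: str | Path = "label",
) -> SpectrumSet:
    """Read a delimited-text spectrum file.

    Parameters
    ----------
    path : path
        CSV/TSV file. For ``samples_as_rows`` the header row holds
        wavenumbers (plus optional ``sample_id`` and label columns) and
        each subsequent row is one sample. For ``samples_as_cols`` the
        first column holds wavenumbers and each further column is one
        sample; labels then come from a ``label`` row or a sidecar file.
    layout : {"samples_as_rows", "samples_as_cols"}
    label_source : str or path
        Name of the label column (row-layout) or path to a two-column
        ``sample_id,label`` sidecar file.

    Returns
    -------
    SpectrumSet
        With a strictly decreasing grid; ascending input is reversed
        (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")
    sep = _sniff_delimiter(first)

    if layout == "samples_as_rows":
        return _read_rows(path, sep, label_source)
    if layout == "samples_as_cols":
        return _read_cols(path, sep, label_source)
    raise ConfigError(f"unknown layout {layout!r}")


def _finalize(wn: np.ndarray, absorb: np.ndarray, labels, ids, path) -> SpectrumSet:
    if wn.size > 1 and wn[0] < wn[-1]:
        logger.info("%s: ascending wavenumbers reversed to spectrometer order", path)
        wn = wn[::-1]
        absorb = absorb[:, ::-1]
    grid = WavenumberGrid.from_values(wn)
    return SpectrumSet(grid=grid, absorbance=absorb, labels=np.asarray(labels, dtype=object),
                       sample_ids=list(ids))


def _read_rows(path: Path, sep: str, label_source) -> SpectrumSet:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    header = rows[0]
    widths = {len(r) for r in rows[1:] if r}
    if len(widths) > 1 or (widths and widths != {len(header)}):
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")

    wn_cols, meta_cols = [], {}
    for j, name in enumerate(header):
        try:
            float(name)
            wn_cols.append(j)
        except ValueError:
            meta_cols[name.strip()] = j

    if not wn_cols:
        raise FormatError(f"{path}: header contains no numeric wavenumbers")
    wn = np.array([float(header[j]) for j in wn_cols])

    label_col = None
    sidecar = None
    ls = str(label_source)
    if ls in meta_cols:
        label_col = meta_cols[ls]
    elif Path(ls).exists() and Path(ls).is_file():
        sidecar = _load_sidecar_labels(Path(ls))

    id_col = meta_cols.get("sample_id")
    data, labels, ids = [], [], []
    for i, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        vals = []
        for j in wn_cols:
            try:
                vals.append(float(row[j]))
            except ValueError:
                raise ParseError(f"{path}: non-numeric absorbance at row {i}, col {j + 1}: {row[j]!r}")
        data.append(vals)
        sid = row[id_col] if id_col is not None else f"s{len(ids)}"
        ids.append(sid)
        if label_col is not None:
            lab = row[label_col].strip()
            if not lab:
                raise LabelingError(f"{path}: missing label at row {i}")
            labels.append(lab)
        elif sidecar is not None:
            if sid not in sidecar:
                raise LabelingError(f"{path}: no sidecar label for sample {sid!r}")
            labels.append(sidecar[sid])
        else:
            raise LabelingError(
                f"{path}: no label column {ls!r} and no sidecar file at that path"
            )
    absorb = np.array(data, dtype=float) if data else np.empty((0, wn.size))
    return _finalize(wn, absorb, labels, ids, path)


def _read_cols(path: Path, sep: str, label_source) -> SpectrumSet:
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: column layout needs wavenumbers plus >= 1 sample")
    ids = [c.strip() for c in df.columns[1:]]
    label_row = df.iloc[:, 0].astype(str).str.strip().str.lower() == "label"
    labels: list[str]
    if label_row.any():
        labels = [str(v) for v in df.loc[label_row].iloc[0, 1:]]
        df = df.loc[~label_row]
    else:
        sidecar_path = Path(str(label_source))
        if not sidecar_path.is_file():
            raise LabelingError(f"{path}: column layout needs a 'label' row or sidecar file")
        sidecar = _load_sidecar_labels(sidecar_path)
        missing = [s for s in ids if s not in sidecar]
        if missing:
            raise LabelingError(f"{path}: no sidecar label for samples {missing}")
        labels = [sidecar[s] for s in ids]
    try:
        wn = df.iloc[:, 0].astype(float).to_numpy()
        absorb = df.iloc[:, 1:].astype(float).to_numpy().T
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric value in column layout: {e}")
    return _finalize(wn, absorb, labels, ids, path)


def write_spectra(s: SpectrumSet, path: str | Path) -> Path:
    """Write a SpectrumSet as CSV (samples as rows), re-readable losslessly.

    Layout: ``sample_id,label,<wn_0>,...,<wn_last>`` header, one row per
    sample, full float precision.
    """
    path = Path(path)
    wn = s.grid.values
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "label"] + [_FLOAT_FMT % v for v in wn])
        for i in range(s.n_samples):
            w.writerow(
                [s.sample_ids[i], s.labels[i]]
                + [_FLOAT_FMT % v for v in s.absorbance[i]]
            )
    return path


# ---------------------------------------------------------------------------
# JCAMP-DX-style single-spectrum format
# ---------------------------------------------------------------------------

def read_jcampdx(path: str | Path, label: str | None = None) -> SpectrumSet:
    """Read one spectrum from a minimal JCAMP-DX file.

    Honors ``##XUNITS=1/CM``, ``##XFACTOR``, ``##YFACTOR``, ``##FIRSTX``,
    ``##LASTX``, ``##NPOINTS`` and tabular ``##XYDATA=(X++(Y..Y))``
    records. Compressed (DIF/DUP/SQZ) encodings are not supported.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    ydata: list[float] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XYDATA":
                    if "(X++(Y..Y))" not in val.replace(" ", ""):
                        raise FormatError(f"{path}: unsupported XYDATA form {val!r}")
                    in_table = True
                    continue
                if key == "END":
                    in_table = False
                fields[key] = val
                continue
            if in_table:
                toks = re.split(r"[,\s]+", line)
                try:
                    nums = [float(t) for t in toks if t]
                except ValueError:
                    raise ParseError(f"{path}: non-numeric XYDATA line {line!r}")
                ydata.extend(nums[1:])  # first token is the abscissa

    xunits = fields.get("XUNITS", "1/CM").upper()
    if xunits not in ("1/CM", "1/ CM"):
        raise FormatError(f"{path}: expected ##XUNITS=1/CM, got {xunits!r}")
    try:
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
        npoints = int(float(fields["NPOINTS"]))
    except KeyError as e:
        raise FormatError(f"{path}: missing required JCAMP field {e}")
    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))

    if len(ydata) != npoints:
        raise FormatError(f"{path}: NPOINTS={npoints} but {len(ydata)} ordinates read")
    wn = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.asarray(ydata, dtype=float) * yfactor
    if label is None:
        label = fields.get("TITLE", path.stem)
    return _finalize(wn, y[None, :], [label], [path.stem], path)


def write_jcampdx(s: SpectrumSet, path: str | Path, sample: int = 0) -> Path:
    """Write one sample of a SpectrumSet as a minimal JCAMP-DX file."""
    path = Path(path)
    wn = s.grid.values
    y = s.absorbance[sample]
    with open(path, "w") as fh:
        fh.write(f"##TITLE={s.sample_ids[sample]}\n")
        fh.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
        fh.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        fh.write(f"##FIRSTX={_FLOAT_FMT % wn[0]}\n##LASTX={_FLOAT_FMT % wn[-1]}\n")
        fh.write(f"##NPOINTS={wn.size}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        for start in range(0, wn.size, 6):
            chunk = y[start:start + 6]
            fh.write(_FLOAT_FMT % wn[start] + " "
                     + " ".join(_FLOAT_FMT % v for v in chunk) + "\n")
        fh.write("##END=\n")
    return path


def read_jcampdx_many(
    paths: Iterable[str | Path],
    label_pattern: str | None = None,
    manifest: Mapping[str, str] | None = None,
) -> SpectrumSet:
    """Read several single-spectrum JCAMP files onto one common grid.

    Labels come from ``manifest`` (stem -> label), a regex
    ``label_pattern`` with one group applied to the file stem, or the
    ##TITLE field.
    """
    sets: list[SpectrumSet] = []
    for p in paths:
        p = Path(p)
        lab = None
        if manifest is not None:
            if p.stem not in manifest:
                raise LabelingError(f"manifest has no label for {p.stem!r}")
            lab = manifest[p.stem]
        elif label_pattern is not None:
            m = re.search(label_pattern, p.stem)
            if not m:
                raise LabelingError(f"{p.stem!r} does not match label pattern")
            lab = m.group(1)
        sets.append(read_jcampdx(p, label=lab))
    if not sets:
        raise FormatError("no JCAMP files given")
    grid = sets[0].grid
    for s in sets[1:]:
        if not s.grid.isclose(grid, atol=1e-6):
            raise FormatError("JCAMP files are not on a common grid")
    return SpectrumSet(
        grid=grid,
        absorbance=np.vstack([s.absorbance for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        sample_ids=[sid for s in sets for sid in s.sample_ids],
    )
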