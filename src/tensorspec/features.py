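"""Characteristic-wavenumber selection from the sparse tensor.

The sparse component's per-class frontal slices are reduced to
nonnegative difference profiles (sum of absolute values across samples
at each wavenumber), the profiles are summed across classes into an
aggregate score Q, and wavenumbers whose (max-normalized) score exceeds
a threshold become the characteristic set used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import BandError, ConfigError, DegenerateInputError, SelectionError
from .io import SpectrumSet, WavenumberGrid
from .trpca import SpectralTensor

__all__ = [
    "DifferenceProfiles",
    "CharacteristicSet",
    "restrict_band",
    "class_difference_profile",
    "aggregate_profiles",
    "profiles_from_sparse",
    "select_characteristic",
    "extract_feature_matrix",
]


@dataclass
class DifferenceProfiles:
    """Per-class difference profiles P (k x n) and aggregate Q (n)."""

    P: np.ndarray
    Q: np.ndarray
    grid: WavenumberGrid

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.P.ndim != 2 or self.Q.shape != (self.P.shape[1],):
            raise ConfigError("P must be k x n with Q of length n")
        if np.any(self.P < 0):
            raise ConfigError("difference profiles must be nonnegative")

    def descending_order(self) -> np.ndarray:
        """Wavenumber indices sorted by aggregate score, highest first."""
        return np.argsort(-self.Q, kind="stable")


@dataclass
class CharacteristicSet:
    """Selected characteristic wavenumbers (ascending grid indices)."""

    indices: np.ndarray
    wavenumbers: np.ndarray
    threshold: float
    normalized: bool
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise SelectionError("characteristic set may not be empty")
        if np.unique(self.indices).size != self.indices.size:
            raise ConfigError("characteristic indices must be unique")

    def __len__(self) -> int:
        return self.indices.size


def _band_slice(grid: WavenumberGrid, nu_hi: float, nu_lo: float) -> tuple[int, int]:
    if nu_hi <= nu_lo:
        raise BandError(f"need nu_hi > nu_lo, got {nu_hi}, {nu_lo}")
    v = grid.values
    eps = 1e-9 * max(1.0, grid.resolution)
    mask = (v >= nu_lo - eps) & (v <= nu_hi + eps)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise BandError(
            f"band [{nu_lo}, {nu_hi}] cm^-1 does not intersect grid "
            f"[{v[-1]:.1f}, {v[0]:.1f}]"
        )
    return int(idx[0]), int(idx[-1] + 1)


def restrict_band(obj, nu_hi: float, nu_lo: float):
    """Keep grid points with ``nu_lo <= nu <= nu_hi`` (inclusive).

    Works on a :class:`SpectrumSet` (slices absorbance columns) or a
    :class:`SpectralTensor` (slices the wavenumber mode).
    """
    if isinstance(obj, SpectrumSet):
        i0, i1 = _band_slice(obj.grid, nu_hi, nu_lo)
        return obj.replace(grid=obj.grid.slice(i0, i1), absorbance=obj.absorbance[:, i0:i1])
    if isinstance(obj, SpectralTensor):
        i0, i1 = _band_slice(obj.grid, nu_hi, nu_lo)
        return SpectralTensor(
            data=obj.data[i0:i1], grid=obj.grid.slice(i0, i1),
            class_order=list(obj.class_order),
        )
    raise TypeError(f"cannot band-restrict {type(obj).__name__}")


def class_difference_profile(E_slice: np.ndarray) -> np.ndarray:
    """Per-wavenumber sum of absolute sparse values across samples.

    ``E_slice`` is one class's n_wavenumbers x m_samples sparse matrix;
    returns the length-n profile p_h with p_hi = sum_j |w_ij|.
    """
    E_slice = np.atleast_2d(np.asarray(E_slice, dtype=float))
    if not np.all(np.isfinite(E_slice)):
        raise ConfigError("sparse slice contains non-finite entries")
    return np.abs(E_slice).sum(axis=1)


def aggregate_profiles(P: np.ndarray) -> np.ndarray:
    """Sum per-class profiles into the aggregate score Q (q_i = sum_h p_hi)."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if np.any(P < 0):
        raise ConfigError("profiles must be nonnegative")
    return P.sum(axis=0)


def profiles_from_sparse(E: SpectralTensor) -> DifferenceProfiles:
    """Build P and Q from the sparse tensor's class slices."""
    P = np.stack([class_difference_profile(E.data[:, :, h]) for h in range(E.shape[2])])
    return DifferenceProfiles(P=P, Q=aggregate_profiles(P), grid=E.grid)


def select_characteristic(
    Q: np.ndarray,
    grid: WavenumberGrid,
    threshold: float = 0.2,
    normalize: bool = True,
) -> CharacteristicSet:
    """Threshold the aggregate score into a characteristic set.

    With ``normalize`` (default) Q is divided by its maximum first, so
    the selection is invariant to the overall scale of the sparse
    component. Strictly greater than the threshold; ties excluded.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 1 or Q.shape[0] != grid.n_points:
        raise ConfigError("Q length must match the grid")
    if np.any(Q < 0):
        raise ConfigError("Q must be nonnegative")
    qmax = Q.max() if Q.size else 0.0
    if normalize:
        if qmax <= 0:
            raise DegenerateInputError("all-zero Q cannot be normalized")
        scores = Q / qmax
    else:
        scores = Q
    idx = np.flatnonzero(scores > threshold)
    if idx.size == 0:
        raise SelectionError(
            f"no score exceeds threshold {threshold}; lower the threshold "
            f"(max score {scores.max() if scores.size else 0:.4g})"
        )
    return CharacteristicSet(
        indices=idx,
        wavenumbers=grid.values[idx],
        threshold=threshold,
        normalized=normalize,
        scores=scores,
    )


def extract_feature_matrix(s: SpectrumSet, cs: CharacteristicSet) -> np.ndarray:
    """Absorbance columns at the characteristic indices (n_samples x |set|)."""
    if cs.indices.max() >= s.n_points or cs.indices.min() < 0:
        raise ConfigError(
            f"characteristic index out of range for {s.n_points}-point grid"
        )
    return s.absorbance[:, cs.indices]
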