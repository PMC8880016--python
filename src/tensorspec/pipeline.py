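"""End-to-end processing chain and its configuration.

Stage order: derivative preprocessing -> band restriction -> class
tensor -> low-rank/sparse decomposition -> characteristic-wavenumber
selection -> SVM cross-validated accuracy. Every stage failure is
re-raised as a :class:`~tensorspec.exceptions.StageError` carrying the
stage name; the report records the dimensionality trail.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold

from .classify import SVMConfig, build_svm, cv_accuracy
from .exceptions import ConfigError, DataError, StageError, StratificationError
from .features import (
    CharacteristicSet,
    extract_feature_matrix,
    profiles_from_sparse,
    restrict_band,
    select_characteristic,
)
from .io import SpectrumSet, read_spectra
from .preprocess import NDFConfig, norris_derivative_filter
from .synthgen import to_tensor
from .trpca import DecompositionResult, TRPCAConfig, trpca_decompose

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "preprocess_band",
    "select_on",
    "leakage_safe_cv",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline settings (defaults = the tuned operating point:
    smoothing window 23, first derivative, 8000-4500 cm^-1 band,
    normalized-score threshold 0.2, polynomial SVM with C = 145)."""

    ndf: NDFConfig = field(default_factory=lambda: NDFConfig(window_N=23, gap_g=1,
                                                             derivative_order=1))
    band: tuple[float, float] = (8000.0, 4500.0)  # (nu_hi, nu_lo)
    trpca: TRPCAConfig = field(default_factory=TRPCAConfig)
    threshold: float = 0.2
    normalize: bool = True
    svm: SVMConfig = field(default_factory=lambda: SVMConfig(C=145.0))
    folds: int = 5
    seed: int = 42
    mode: str = "paper"

    def __post_init__(self):
        if self.mode not in ("paper", "safe"):
            raise ConfigError(f"mode must be 'paper' or 'safe', got {self.mode!r}")
        if not self.band[0] > self.band[1]:
            raise ConfigError(f"band must be (nu_hi, nu_lo), got {self.band}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ndf" in d and isinstance(d["ndf"], dict):
            d["ndf"] = NDFConfig(**d["ndf"])
        if "trpca" in d and isinstance(d["trpca"], dict):
            d["trpca"] = TRPCAConfig(**d["trpca"])
        if "svm" in d and isinstance(d["svm"], dict):
            d["svm"] = SVMConfig(**d["svm"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(f"bad pipeline config: {e}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


@dataclass
class PipelineReport:
    """Results and diagnostics of one pipeline run."""

    accuracy: float
    characteristic: CharacteristicSet
    dimensionality: dict[str, int]
    mode: str
    seed: int
    trpca_iterations: int
    trpca_residual: float
    trpca_converged: bool
    config: dict

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "characteristic_indices": [int(i) for i in self.characteristic.indices],
            "characteristic_wavenumbers": [float(v) for v in self.characteristic.wavenumbers],
            "selection_threshold": self.characteristic.threshold,
            "normalized_scores": self.characteristic.normalized,
            "dimensionality": self.dimensionality,
            "mode": self.mode,
            "seed": self.seed,
            "trpca": {
                "iterations": self.trpca_iterations,
                "final_residual": self.trpca_residual,
                "converged": self.trpca_converged,
            },
            "config": self.config,
        }


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def preprocess_band(raw: SpectrumSet, ndf: NDFConfig, band: tuple[float, float]) -> SpectrumSet:
    """Derivative preprocessing followed by band restriction."""
    processed = norris_derivative_filter(raw, ndf)
    return restrict_band(processed, band[0], band[1])


def select_on(
    processed: SpectrumSet,
    trpca_cfg: TRPCAConfig,
    threshold: float,
    normalize: bool,
) -> tuple[CharacteristicSet, DecompositionResult]:
    """Decompose the class tensor of ``processed`` and select wavenumbers."""
    tensor = to_tensor(processed)
    decomp = trpca_decompose(tensor, trpca_cfg)
    profiles = profiles_from_sparse(decomp.E)
    cs = select_characteristic(profiles.Q, processed.grid, threshold=threshold,
                               normalize=normalize)
    return cs, decomp


def _subset(s: SpectrumSet, idx: np.ndarray) -> SpectrumSet:
    return SpectrumSet(
        grid=s.grid,
        absorbance=s.absorbance[idx],
        labels=s.labels[idx],
        sample_ids=[s.sample_ids[i] for i in idx],
    )


def leakage_safe_cv(
    processed: SpectrumSet,
    trpca_cfg: TRPCAConfig,
    threshold: float,
    normalize: bool,
    svm_cfg: SVMConfig,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, int]:
    """Stratified CV with decomposition + selection inside each training fold.

    Returns (mean held-out accuracy, median number of selected features).
    """
    y = processed.labels.astype(str)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, dims = [], []
    for train_idx, test_idx in skf.split(processed.absorbance, y):
        train = _subset(processed, train_idx)
        cs, _ = select_on(train, trpca_cfg, threshold, normalize)
        dims.append(len(cs))
        model = build_svm(svm_cfg)
        model.fit(extract_feature_matrix(train, cs), train.labels.astype(str))
        test = _subset(processed, test_idx)
        accs.append(model.score(extract_feature_matrix(test, cs), test.labels.astype(str)))
    return float(np.mean(accs)), int(np.median(dims))


def run_pipeline(data: SpectrumSet | str | Path, cfg: PipelineConfig | None = None) -> PipelineReport:
    """Execute the full chain and return a report.

    ``data`` may be a SpectrumSet or a path to a delimited-text file.
    Deterministic for a fixed input, config and seed.
    """
    cfg = cfg or PipelineConfig()
    with _stage("io"):
        raw = data if isinstance(data, SpectrumSet) else read_spectra(data)
    dims = {"raw": raw.n_points}
    with _stage("preprocess"):
        processed = norris_derivative_filter(raw, cfg.ndf)
    dims["post_ndf"] = processed.n_points
    with _stage("band"):
        banded = restrict_band(processed, cfg.band[0], cfg.band[1])
    dims["post_band"] = banded.n_points
    with _stage("tensor"):
        tensor = to_tensor(banded)
    with _stage("trpca"):
        decomp = trpca_decompose(tensor, cfg.trpca)
    with _stage("features"):
        profiles = profiles_from_sparse(decomp.E)
        cs = select_characteristic(profiles.Q, banded.grid, threshold=cfg.threshold,
                                   normalize=cfg.normalize)
        X = extract_feature_matrix(banded, cs)
    dims["characteristic"] = len(cs)
    with _stage("classify"):
        if cfg.mode == "paper":
            acc = cv_accuracy(X, raw.labels.astype(str), cfg.svm, folds=cfg.folds,
                              seed=cfg.seed)
        else:
            acc, _ = leakage_safe_cv(banded, cfg.trpca, cfg.threshold, cfg.normalize,
                                     cfg.svm, folds=cfg.folds, seed=cfg.seed)
    return PipelineReport(
        accuracy=acc,
        characteristic=cs,
        dimensionality=dims,
        mode=cfg.mode,
        seed=cfg.seed,
        trpca_iterations=decomp.iterations,
        trpca_residual=decomp.final_residual,
        trpca_converged=decomp.converged,
        config=cfg.to_dict(),
    )
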