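"""Multi-class SVM on characteristic features, with grid search.

The classifier is a soft-margin SVM with the polynomial kernel
``K(x_i, x_j) = (gamma <x_i, x_j> + r)^q`` (one-vs-one for multi-class),
optionally preceded by per-feature standardization fitted on training
data only. The grid search sweeps the smoothing window of the derivative
preprocessing jointly with the SVM penalty factor C, re-running the full
feature-extraction pipeline per window and scoring by stratified k-fold
cross-validation.

Two protocols are supported: "paper" mode selects characteristic
wavenumbers once on all samples before cross-validation (the apparent
protocol of the original study, optimistically biased), while "safe"
mode re-runs decomposition and selection inside each training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigError, StratificationError, TrainingError
from .io import SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "SVMConfig",
    "GridSearchResult",
    "poly_kernel",
    "build_svm",
    "train_svm",
    "cv_accuracy",
    "grid_search_pipeline",
]


@dataclass(frozen=True)
class SVMConfig:
    """Polynomial-kernel SVM settings.

    ``gamma="auto"`` resolves to ``1 / n_features`` at fit time.
    """

    C: float = 1.0
    kernel_degree: int = 3
    gamma: float | str = "auto"
    coef: float = 1.0
    multiclass: str = "one_vs_one"
    standardize: bool = True

    def __post_init__(self):
        if self.C <= 0:
            raise ConfigError(f"penalty factor C must be positive, got {self.C}")
        if self.kernel_degree < 1:
            raise ConfigError(f"kernel degree must be >= 1, got {self.kernel_degree}")
        if isinstance(self.gamma, str):
            if self.gamma != "auto":
                raise ConfigError(f"gamma must be positive or 'auto', got {self.gamma!r}")
        elif self.gamma <= 0:
            raise ConfigError(f"gamma must be positive, got {self.gamma}")
        if self.multiclass not in ("one_vs_one", "one_vs_rest"):
            raise ConfigError(f"unknown multiclass scheme {self.multiclass!r}")


def poly_kernel(x_i: np.ndarray, x_j: np.ndarray, gamma: float = 1.0,
                r: float = 1.0, q: int = 3) -> float:
    """Polynomial kernel ``(gamma <x_i, x_j> + r)^q`` between two vectors."""
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape != x_j.shape:
        raise ConfigError(f"vector lengths differ: {x_i.shape} vs {x_j.shape}")
    return float((gamma * np.dot(x_i, x_j) + r) ** q)


def build_svm(cfg: SVMConfig | None = None):
    """Unfitted sklearn estimator implementing the configured SVM."""
    cfg = cfg or SVMConfig()
    svc = SVC(
        C=cfg.C,
        kernel="poly",
        degree=cfg.kernel_degree,
        gamma=cfg.gamma,  # sklearn "auto" == 1 / n_features
        coef0=cfg.coef,
    )
    clf = OneVsRestClassifier(svc) if cfg.multiclass == "one_vs_rest" else svc
    if cfg.standardize:
        return Pipeline([("scale", StandardScaler()), ("svm", clf)])
    return clf


def train_svm(X: np.ndarray, y: Sequence, cfg: SVMConfig | None = None):
    """Fit the SVM; raises TrainingError on degenerate label sets."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ConfigError(f"X is {X.shape} but y has {y.shape[0]} labels")
    if not np.all(np.isfinite(X)):
        raise ConfigError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise TrainingError("training requires at least two classes")
    model = build_svm(cfg)
    model.fit(X, y)
    return model


def cv_accuracy(X: np.ndarray, y: Sequence, cfg: SVMConfig | None = None,
                folds: int = 5, seed: int = 0) -> float:
    """Mean stratified k-fold held-out accuracy, deterministic per seed."""
    if folds < 2:
        raise ConfigError(f"need folds >= 2, got {folds}")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2:
        raise TrainingError("cross-validation requires at least two classes")
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(build_svm(cfg), np.asarray(X, dtype=float), y, cv=skf)
    return float(scores.mean())


@dataclass
class GridSearchResult:
    """Outcome of the window x penalty sweep."""

    table: pd.DataFrame  # columns: window_N, C, accuracy
    best: tuple[int, float, float] | None  # (window_N, C, accuracy); None if all failed
    n_features_by_window: dict[int, int]
    folds: int
    seed: int
    mode: str = "paper"
    diagnostics: dict = field(default_factory=dict)


def _pick_best(table: pd.DataFrame) -> tuple[int, float, float] | None:
    valid = table.dropna(subset=["accuracy"])
    if valid.empty:
        logger.warning("every grid point failed; no best configuration")
        return None
    # max accuracy; ties broken by smaller C, then smaller window
    ordered = valid.sort_values(
        ["accuracy", "C", "window_N"], ascending=[False, True, True], kind="stable"
    )
    top = ordered.iloc[0]
    n_top = int((valid["accuracy"] == top["accuracy"]).sum())
    if n_top > 1:
        logger.info(
            "grid search: %d configurations tie at accuracy %.4f; "
            "choosing smallest C then smallest window (C=%g, window=%d)",
            n_top, top["accuracy"], top["C"], int(top["window_N"]),
        )
    return int(top["window_N"]), float(top["C"]), float(top["accuracy"])


def grid_search_pipeline(
    raw: SpectrumSet,
    windows: Sequence[int],
    Cs: Sequence[float],
    pipe_cfg=None,
    folds: int = 5,
    seed: int = 0,
    mode: str = "paper",
) -> GridSearchResult:
    """Sweep smoothing window and penalty factor over the full pipeline.

    For each window the derivative preprocessing, band restriction,
    tensor decomposition and characteristic selection are re-run; every
    penalty is then scored by stratified CV on the resulting features. A
    window whose selection empties out is recorded with NaN accuracy
    rather than aborting the sweep.
    """
    from .pipeline import (  # local import to avoid a module cycle
        PipelineConfig,
        leakage_safe_cv,
        preprocess_band,
        select_on,
    )
    from .exceptions import DataError
    from .features import extract_feature_matrix

    if not windows or not Cs:
        raise ConfigError("windows and Cs must be non-empty")
    if mode not in ("paper", "safe"):
        raise ConfigError(f"mode must be 'paper' or 'safe', got {mode!r}")
    pipe_cfg = pipe_cfg or PipelineConfig()

    rows = []
    n_features: dict[int, int] = {}
    for w in windows:
        ndf = replace(pipe_cfg.ndf, window_N=int(w))
        try:
            processed = preprocess_band(raw, ndf, pipe_cfg.band)
            if mode == "paper":
                cs, _ = select_on(processed, pipe_cfg.trpca, pipe_cfg.threshold,
                                  pipe_cfg.normalize)
                n_features[int(w)] = len(cs)
                X = extract_feature_matrix(processed, cs)
                for C in Cs:
                    svm = replace(pipe_cfg.svm, C=float(C))
                    acc = cv_accuracy(X, raw.labels, svm, folds=folds, seed=seed)
                    rows.append((int(w), float(C), acc))
            else:
                n_sel = None
                for C in Cs:
                    svm = replace(pipe_cfg.svm, C=float(C))
                    acc, n_sel = leakage_safe_cv(
                        processed, pipe_cfg.trpca, pipe_cfg.threshold,
                        pipe_cfg.normalize, svm, folds=folds, seed=seed,
                    )
                    rows.append((int(w), float(C), acc))
                n_features[int(w)] = int(n_sel) if n_sel is not None else 0
        except DataError as e:
            logger.warning("window %d failed: %s", w, e)
            n_features[int(w)] = 0
            for C in Cs:
                rows.append((int(w), float(C), np.nan))

    table = pd.DataFrame(rows, columns=["window_N", "C", "accuracy"])
    best = _pick_best(table)
    return GridSearchResult(
        table=table, best=best, n_features_by_window=n_features,
        folds=folds, seed=seed, mode=mode,
    )
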