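"""Third-order tensor robust principal component analysis.

Decomposes a spectral tensor ``D`` (wavenumbers x samples x classes)
into a low-tubal-rank part ``A`` carrying the spectral structure common
to all classes and a sparse part ``E`` carrying class-differential
features, by solving

    min  ||A||_TNN + eta * ||E||_1   subject to  D = A + E

with an augmented-Lagrangian ADMM. ``||.||_TNN`` is the tubal tensor
nuclear norm of the t-SVD: take the DFT along the class mode, sum the
matrix nuclear norms of the transformed frontal slices, and divide by
the number of classes. Its proximal operator applies singular-value
soft-thresholding slice-wise in the Fourier domain; the l1 proximal
operator is elementwise soft-thresholding.

The sparsity weight defaults to the standard TRPCA choice
``eta = 1 / sqrt(max(w, s) * c)``; the variant without the radical is
available as ``eta_rule="literal"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from .exceptions import ConfigError, DataError
from .io import WavenumberGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralTensor",
    "TRPCAConfig",
    "DecompositionResult",
    "default_eta",
    "soft_threshold",
    "matrix_svt",
    "tensor_svt",
    "trpca_decompose",
    "save_tensor",
    "load_tensor",
]


@dataclass
class SpectralTensor:
    """Third-order spectral array: wavenumbers x samples-per-class x classes.

    Frontal slice ``data[:, :, h]`` is the spectral matrix of class
    ``class_order[h]``.
    """

    data: np.ndarray
    grid: WavenumberGrid
    class_order: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError(f"spectral tensor must be 3-D, got shape {self.data.shape}")
        if self.data.shape[0] != self.grid.n_points:
            raise DataError(
                f"tensor has {self.data.shape[0]} wavenumbers but grid has "
                f"{self.grid.n_points}"
            )
        if self.data.shape[2] != len(self.class_order):
            raise DataError(
                f"tensor has {self.data.shape[2]} slices but {len(self.class_order)} classes"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("spectral tensor contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def replace_data(self, data: np.ndarray) -> "SpectralTensor":
        return SpectralTensor(data=data, grid=self.grid, class_order=list(self.class_order))


@dataclass(frozen=True)
class TRPCAConfig:
    """ADMM settings for the low-rank + sparse split.

    ``eta=None`` resolves to :func:`default_eta` for the tensor's shape.
    The penalty ``mu`` starts at ``mu0`` and grows by ``rho`` each
    iteration up to ``mu_max``; iteration stops when the relative
    residual ``||D - A - E||_F / ||D||_F`` falls below ``tol``.
    """

    eta: float | None = None
    eta_rule: str = "sqrt"
    mu0: float = 1e-3
    rho: float = 1.1
    mu_max: float = 1e10
    tol: float = 1e-7
    max_iter: int = 500

    def __post_init__(self):
        if self.eta is not None and self.eta <= 0:
            raise ConfigError(f"eta must be positive, got {self.eta}")
        if self.eta_rule not in ("sqrt", "literal"):
            raise ConfigError(f"eta_rule must be 'sqrt' or 'literal', got {self.eta_rule!r}")
        if self.mu0 <= 0 or self.rho < 1 or self.tol <= 0 or self.max_iter < 1:
            raise ConfigError("need mu0 > 0, rho >= 1, tol > 0, max_iter >= 1")


@dataclass
class DecompositionResult:
    """Low-rank/sparse split plus convergence diagnostics."""

    A: SpectralTensor
    E: SpectralTensor
    iterations: int
    final_residual: float
    converged: bool
    dual: np.ndarray
    eta: float
    residual_history: list[float] = field(default_factory=list)


def save_tensor(T: SpectralTensor, path, extra: dict | None = None):
    """Serialize a tensor (plus optional named companions) to ``.npz``."""
    arrays = dict(
        data=T.data,
        nu_max=np.array(T.grid.nu_max),
        resolution=np.array(T.grid.resolution),
        n_points=np.array(T.grid.n_points),
        class_order=np.array(T.class_order, dtype=str),
    )
    if extra:
        arrays.update(extra)
    np.savez_compressed(path, **arrays)
    return path


def load_tensor(path) -> SpectralTensor:
    """Read a tensor written by :func:`save_tensor`."""
    with np.load(path, allow_pickle=False) as z:
        grid = WavenumberGrid(
            nu_max=float(z["nu_max"]),
            resolution=float(z["resolution"]),
            n_points=int(z["n_points"]),
        )
        return SpectralTensor(
            data=z["data"], grid=grid, class_order=[str(c) for c in z["class_order"]]
        )


def default_eta(w: int, s: int, c: int, rule: str = "sqrt") -> float:
    """Sparsity weight for a ``w x s x c`` tensor.

    ``sqrt`` rule (default): ``1 / sqrt(max(w, s) * c)``, the standard
    TRPCA convention. ``literal`` rule: ``1 / (max(w, s) * c)``.
    """
    if min(w, s, c) < 1:
        raise ConfigError(f"tensor dims must be >= 1, got {(w, s, c)}")
    prod = max(w, s) * c
    if rule == "sqrt":
        return 1.0 / sqrt(prod)
    if rule == "literal":
        return 1.0 / prod
    raise ConfigError(f"unknown eta rule {rule!r}")


def soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage ``sign(x) * max(|x| - tau, 0)`` (l1 prox)."""
    if tau < 0:
        raise ConfigError(f"threshold must be >= 0, got {tau}")
    x = np.asarray(x)
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def matrix_svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding (nuclear-norm prox).

    Works for real or complex matrices; returns
    ``U diag(max(sigma - tau, 0)) V^H``.
    """
    if tau < 0:
        raise ConfigError(f"threshold must be >= 0, got {tau}")
    M = np.asarray(M)
    if not np.all(np.isfinite(M)):
        raise DataError("matrix_svt input contains non-finite entries")
    U, sig, Vh = np.linalg.svd(M, full_matrices=False)
    sig = np.maximum(sig - tau, 0.0)
    keep = sig > 0
    if not keep.any():
        return np.zeros_like(M)
    return (U[:, keep] * sig[keep]) @ Vh[keep]


def _tensor_svt_data(T: np.ndarray, tau: float) -> np.ndarray:
    """Prox of the tubal tensor nuclear norm on a raw 3-D array."""
    c = T.shape[2]
    F = np.fft.fft(T, axis=2)
    out = np.empty_like(F)
    half = c // 2 + 1
    for k in range(half):
        out[:, :, k] = matrix_svt(F[:, :, k], tau)
    # conjugate symmetry of the DFT of a real tensor
    for k in range(half, c):
        out[:, :, k] = np.conj(out[:, :, c - k])
    res = np.fft.ifft(out, axis=2)
    imag_max = float(np.abs(res.imag).max()) if res.size else 0.0
    if imag_max > 1e-8 * max(1.0, float(np.abs(res.real).max())):
        warnings.warn(f"tensor_svt imaginary residue {imag_max:.3e}")
    return np.ascontiguousarray(res.real)


def tensor_svt(T: SpectralTensor, tau: float) -> SpectralTensor:
    """Tensor singular-value thresholding via the t-SVD.

    DFT along the class mode, :func:`matrix_svt` with threshold ``tau``
    on each transformed frontal slice, inverse transform. For a single
    class this reduces exactly to :func:`matrix_svt`.
    """
    if tau < 0:
        raise ConfigError(f"threshold must be >= 0, got {tau}")
    return T.replace_data(_tensor_svt_data(T.data, tau))


def trpca_decompose(D: SpectralTensor, cfg: TRPCAConfig | None = None) -> DecompositionResult:
    """Split ``D`` into low-tubal-rank ``A`` plus sparse ``E`` by ADMM.

    Per iteration: ``A``-update = tensor SVT with threshold ``1/mu`` on
    ``D - E + y/mu``; ``E``-update = soft threshold ``eta/mu`` on
    ``D - A + y/mu``; dual ``y += mu (D - A - E)``; ``mu`` grows by
    ``rho``. Non-convergence within ``max_iter`` returns a result with
    ``converged=False`` and a warning, not an exception.
    """
    cfg = cfg or TRPCAConfig()
    d = D.data
    w, s, c = d.shape
    eta = cfg.eta if cfg.eta is not None else default_eta(w, s, c, cfg.eta_rule)

    norm_d = float(np.linalg.norm(d))
    A = np.zeros_like(d)
    E = np.zeros_like(d)
    Y = np.zeros_like(d)
    if norm_d == 0.0:
        return DecompositionResult(
            A=D.replace_data(A), E=D.replace_data(E), iterations=1,
            final_residual=0.0, converged=True, dual=Y, eta=eta,
            residual_history=[0.0],
        )

    mu = cfg.mu0
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        A = _tensor_svt_data(d - E + Y / mu, 1.0 / mu)
        E = soft_threshold(d - A + Y / mu, eta / mu)
        R = d - A - E
        Y = Y + mu * R
        res = float(np.linalg.norm(R)) / norm_d
        history.append(res)
        if res <= cfg.tol:
            converged = True
            break
        mu = min(cfg.rho * mu, cfg.mu_max)

    if not converged:
        warnings.warn(
            f"TRPCA did not reach tol={cfg.tol:g} in {cfg.max_iter} iterations "
            f"(residual {history[-1]:.3e})"
        )
    logger.debug("TRPCA %s: %d iterations, residual %.3e", d.shape, it, history[-1])
    return DecompositionResult(
        A=D.replace_data(A), E=D.replace_data(E), iterations=it,
        final_residual=history[-1], converged=converged, dual=Y, eta=eta,
        residual_history=history,
    )
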