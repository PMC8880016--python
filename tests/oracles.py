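"""Independent reference implementations used only to cross-check results.

These deliberately take different computational routes from the package:
the matrix robust-PCA oracle follows the classic inexact augmented
Lagrange multiplier schedule (dual initialized from the scaled data,
``mu0 = 1.25 / ||D||_2``, growth 1.5), and the tensor
singular-value-thresholding oracle works on the explicit block-circulant
matrix instead of slice-wise in the Fourier domain.
"""

from __future__ import annotations

import numpy as np


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    U, s, Vh = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vh


def shrink(X: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(X) * np.maximum(np.abs(X) - tau, 0.0)


def matrix_rpca_ialm(D: np.ndarray, lam: float, tol: float = 1e-8,
                     max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Matrix robust PCA by the inexact ALM of Lin, Chen & Ma (2010).

    Penalty growth 1.2 rather than the original 1.5: on some planted
    instances the faster schedule freezes a suboptimal split before the
    shrinkage steps settle.
    """
    norm_two = np.linalg.norm(D, 2)
    norm_inf = np.abs(D).max() / lam
    Y = D / max(norm_two, norm_inf)
    mu = 1.25 / norm_two
    mu_bar = mu * 1e9
    rho = 1.2
    normD = np.linalg.norm(D)
    E = np.zeros_like(D)
    for _ in range(max_iter):
        A = svt(D - E + Y / mu, 1.0 / mu)
        E = shrink(D - A + Y / mu, lam / mu)
        Z = D - A - E
        Y = Y + mu * Z
        mu = min(mu * rho, mu_bar)
        if np.linalg.norm(Z) / normD < tol:
            break
    return A, E


def bcirc(T: np.ndarray) -> np.ndarray:
    """Block-circulant unfolding of a (w, s, c) tensor into (w*c, s*c)."""
    w, s, c = T.shape
    B = np.zeros((w * c, s * c))
    for k in range(c):
        for l in range(c):
            B[k * w:(k + 1) * w, l * s:(l + 1) * s] = T[:, :, (k - l) % c]
    return B


def bcirc_tensor_svt(T: np.ndarray, tau: float) -> np.ndarray:
    """Tubal nuclear-norm prox computed on the explicit block-circulant.

    The prox of ``tau * (1/c) ||bcirc(X)||_*`` at Y applies matrix SVT
    with threshold ``tau`` to ``bcirc(Y)``; the result stays block
    circulant, and the tensor is read back by averaging the circulant
    block diagonals (exact up to roundoff).
    """
    w, s, c = T.shape
    B = svt(bcirc(T), tau)
    out = np.zeros_like(T)
    for k in range(c):
        acc = np.zeros((w, s))
        for l in range(c):
            kk = (k + l) % c
            acc += B[kk * w:(kk + 1) * w, l * s:(l + 1) * s]
        out[:, :, k] = acc / c
    return out


def planted_tensor(w: int, s: int, c: int, spike_frac: float, rng: np.random.Generator,
                   spike_amp: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tubal-rank-1 tensor (smooth CP factors) plus random +-amp spikes."""
    t1 = np.linspace(0, 1, w)
    u = np.sin(2 * np.pi * t1) + 1.5 * np.exp(-0.5 * ((t1 - 0.4) / 0.12) ** 2)
    t2 = np.linspace(0, 1, s)
    v = 1.0 + 0.3 * np.cos(2 * np.pi * t2)
    wv = 1.0 - 0.2 * np.arange(c)
    A0 = u[:, None, None] * v[None, :, None] * wv[None, None, :]
    mask = rng.random((w, s, c)) < spike_frac
    E0 = mask * rng.choice([-spike_amp, spike_amp], size=(w, s, c))
    return A0 + E0, A0, E0
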