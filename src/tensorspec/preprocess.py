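"""Norris derivative filtering: van-average smoothing + gap derivative.

The smoothing step partitions each spectrum into consecutive,
non-overlapping fragments of ``window_N`` raw points and replaces every
fragment by its mean (block decimation), so the output has
``floor(n_points / window_N)`` points and its grid points are the
fragment-mean wavenumbers. A trailing fragment shorter than ``window_N``
is dropped so all fragments have identical support.

The derivative step is the direct-difference form
``x'_k = (x_{k+g} - x_{k-g}) / (2 g)`` in fragment-index units, dropping
the ``g`` leading and trailing points. ``scale_by_wavenumber=True``
additionally divides by the grid spacing in cm^-1 to give d(abs)/d(nu).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DegenerateInputError
from .io import SpectrumSet

logger = logging.getLogger(__name__)

__all__ = ["NDFConfig", "van_average_smooth", "first_derivative", "norris_derivative_filter"]


@dataclass(frozen=True)
class NDFConfig:
    """Norris derivative filter settings.

    window_N
        Raw points per smoothing fragment ("smoothing points"); 1 leaves
        the spectrum untouched.
    gap_g
        Derivative half-width in fragment-index units.
    derivative_order
        0 = smoothing only, 1 = smoothing followed by first derivative.
    scale_by_wavenumber
        Divide the derivative by the fragment-grid spacing in cm^-1.
    """

    window_N: int = 1
    gap_g: int = 1
    derivative_order: int = 1
    scale_by_wavenumber: bool = False

    def __post_init__(self):
        if self.window_N < 1:
            raise ConfigError(f"window_N must be >= 1, got {self.window_N}")
        if self.derivative_order not in (0, 1):
            raise ConfigError(f"derivative_order must be 0 or 1, got {self.derivative_order}")
        if self.derivative_order == 1 and self.gap_g < 1:
            raise ConfigError(f"gap_g must be >= 1, got {self.gap_g}")


def van_average_smooth(s: SpectrumSet, window_N: int) -> SpectrumSet:
    """Block-decimate each spectrum by fragment means.

    Returns a SpectrumSet with ``floor(n_points / window_N)`` points;
    each output grid point is the mean wavenumber of its fragment.
    ``window_N=1`` returns the input unchanged.
    """
    if window_N < 1:
        raise ConfigError(f"window_N must be >= 1, got {window_N}")
    n = s.n_points
    if window_N > n:
        raise DegenerateInputError(f"window_N={window_N} exceeds n_points={n}")
    if window_N == 1:
        return s.replace()
    n_frag = n // window_N
    kept = n_frag * window_N
    if kept < n:
        logger.debug("dropping %d-point tail fragment (window_N=%d)", n - kept, window_N)
    smoothed = s.absorbance[:, :kept].reshape(s.n_samples, n_frag, window_N).mean(axis=2)
    # fragment-mean wavenumber: start shifts by (N-1)/2 steps, spacing scales by N
    grid = s.grid
    new_grid = type(grid)(
        nu_max=grid.nu_max - grid.resolution * (window_N - 1) / 2.0,
        resolution=grid.resolution * window_N,
        n_points=n_frag,
    )
    return s.replace(grid=new_grid, absorbance=smoothed)


def first_derivative(s: SpectrumSet, gap_g: int = 1, scale_by_wavenumber: bool = False) -> SpectrumSet:
    """Direct-difference first derivative with half-width ``gap_g``.

    Output drops ``gap_g`` points at each end; grid restricted to the
    interior accordingly.
    """
    if gap_g < 1:
        raise ConfigError(f"gap_g must be >= 1, got {gap_g}")
    n = s.n_points
    if n < 2 * gap_g + 1:
        raise DegenerateInputError(f"need n_points >= {2 * gap_g + 1}, got {n}")
    x = s.absorbance
    deriv = (x[:, 2 * gap_g:] - x[:, : n - 2 * gap_g]) / (2.0 * gap_g)
    if scale_by_wavenumber:
        deriv = deriv / s.grid.resolution
    return s.replace(grid=s.grid.slice(gap_g, n - gap_g), absorbance=deriv)


def norris_derivative_filter(s: SpectrumSet, cfg: NDFConfig) -> SpectrumSet:
    """Smoothing followed (for order 1) by the gap derivative."""
    out = van_average_smooth(s, cfg.window_N)
    if cfg.derivative_order == 1:
        out = first_derivative(out, cfg.gap_g, cfg.scale_by_wavenumber)
    logger.debug(
        "NDF window_N=%d order=%d g=%d: %d -> %d points",
        cfg.window_N, cfg.derivative_order, cfg.gap_g, s.n_points, out.n_points,
    )
    return out
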