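"""Uniform resampling of the RR tachogram and finite-difference derivatives.

The irregular RR series is interpolated with a natural cubic spline and
evaluated on a uniform grid (4 Hz by default).  First derivatives use the
central difference

    d[k] = (u[k+1] - u[k-1]) / (2 Δt)            [ms/s]

and second derivatives the standard three-point stencil

    a[k] = (u[k+1] - 2 u[k] + u[k-1]) / Δt²      [ms/s²]

both defined at interior grid points only (each differentiation shortens the
signal by two samples).  Quality-masked RR runs create gaps: gaps longer than
``max_gap_s`` split the tachogram into independently resampled blocks, so the
spline never bridges (and the stencils never see) fabricated dynamics across
artifact gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .ecg import RRISeries
from .errors import InsufficientDataError

DEFAULT_RATE_HZ = 4.0


@dataclass
class UniformSignal:
    """Equispaced signal: values[k] sits at ``start_s + k / rate``."""

    start_s: float
    rate: float
    values: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(len(self.values)) / self.rate


def _spline_block(times: np.ndarray, rr: np.ndarray, rate: float) -> UniformSignal | None:
    if len(times) < 4:
        return None
    spline = CubicSpline(times, rr, bc_type="natural")
    k0 = int(np.ceil(times[0] * rate - 1e-9))
    k1 = int(np.floor(times[-1] * rate + 1e-9))
    if k1 < k0:
        return None
    grid = np.arange(k0, k1 + 1) / rate
    return UniformSignal(start_s=grid[0], rate=rate, values=spline(grid))


def resample_rr_uniform(rr: RRISeries, rate: float = DEFAULT_RATE_HZ,
                        max_gap_s: float = 5.0) -> list[UniformSignal]:
    """Natural-cubic-spline resampling of the retained tachogram.

    Each RR value is anchored at its interval's end-beat time.  The grid sits
    on multiples of 1/rate inside the data span (no extrapolation).  Returns
    one block per gap-free run; a clean series yields a single block.
    """
    t, v = rr.retained()
    if len(t) < 4:
        raise InsufficientDataError("cubic spline resampling needs >= 4 retained RR values")
    gaps = np.flatnonzero(np.diff(t) > max_gap_s)
    bounds = np.concatenate(([0], gaps + 1, [len(t)]))
    blocks = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        blk = _spline_block(t[a:b], v[a:b], rate)
        if blk is not None:
            blocks.append(blk)
    if not blocks:
        raise InsufficientDataError("no gap-free run long enough to resample")
    return blocks


def first_derivative(u: UniformSignal) -> UniformSignal:
    """Central-difference first derivative at interior points (ms/s)."""
    if len(u.values) < 3:
        raise InsufficientDataError("first derivative needs >= 3 samples")
    dt = 1.0 / u.rate
    d = (u.values[2:] - u.values[:-2]) / (2.0 * dt)
    return UniformSignal(start_s=u.start_s + dt, rate=u.rate, values=d)


def second_derivative(u: UniformSignal) -> UniformSignal:
    """Three-point-stencil second derivative at interior points (ms/s²)."""
    if len(u.values) < 3:
        raise InsufficientDataError("second derivative needs >= 3 samples")
    dt = 1.0 / u.rate
    a = (u.values[2:] - 2.0 * u.values[1:-1] + u.values[:-2]) / dt**2
    return UniformSignal(start_s=u.start_s + dt, rate=u.rate, values=a)


def derivative_blocks(blocks: list[UniformSignal]):
    """First and second derivatives for every block long enough to support them."""
    d1 = [first_derivative(b) for b in blocks if len(b.values) >= 3]
    d2 = [second_derivative(b) for b in blocks if len(b.values) >= 3]
    return d1, d2
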