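"""Reference-tissue kinetic primitives shared by the simulator and the fitter.

The simplified reference tissue model (SRTM) writes a target tissue curve as

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * [C_R (x) exp(-k2a t)](t)

with k2a = k2 / (1 + BP_ND). All rate constants are in 1/min and times in
minutes. Curves are evaluated on a fine regular grid and then averaged over
acquisition frames; frame mid-times are never used as point samples, because
the short early frames of a dynamic amyloid scan make midpoint sampling
biased during the fast uptake phase.

The exponential convolution uses the exact solution for a piecewise-linear
input on a uniform grid (a first-order recursive filter), so it is accurate
to the interpolation error of the input curve rather than to a quadrature
rule's step error.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

DEFAULT_FINE_DT_S = 0.1

__all__ = [
    "fine_time_grid",
    "expconv",
    "srtm_tissue_curve",
    "frame_average_curve",
    "biexp_reference",
    "biexp_frame_means",
]


def fine_time_grid(total_s: float, dt_s: float = DEFAULT_FINE_DT_S) -> np.ndarray:
    """Uniform time grid in minutes covering [0, total_s] at dt_s resolution."""
    n = int(round(total_s / dt_s))
    return np.arange(n + 1) * (dt_s / 60.0)


def expconv(theta: float, t_min: np.ndarray, c: np.ndarray) -> np.ndarray:
    """[c (x) exp(-theta t)] on a uniform grid, exact for piecewise-linear c.

    Parameters
    ----------
    theta : decay rate of the kernel, 1/min (> 0)
    t_min : uniform time grid, minutes
    c : input curve sampled on t_min
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    dt = t_min[1] - t_min[0]
    a = np.exp(-theta * dt)
    # Integral over one step of a linear segment against the decaying kernel:
    # y_{i} = a*y_{i-1} + g1*c_{i-1} + g2*c_{i}
    g2 = 1.0 / theta - (1.0 - a) / (theta * theta * dt)
    g1 = (1.0 - a) / theta - g2
    y = lfilter([g2, g1], [1.0, -a], np.asarray(c, dtype=float))
    y[0] = 0.0
    return y


def srtm_tissue_curve(
    r1: float, k2: float, bp_nd: float, ref_fine: np.ndarray, t_min: np.ndarray
) -> np.ndarray:
    """Forward SRTM operational equation on the fine grid."""
    k2a = k2 / (1.0 + bp_nd)
    conv = expconv(k2a, t_min, ref_fine)
    return r1 * ref_fine + (k2 - r1 * k2a) * conv


def frame_average_curve(values: np.ndarray, t_min: np.ndarray, schedule) -> np.ndarray:
    """Average a fine-grid curve over each frame of the schedule.

    Uses the mean of all fine samples within [start, end] of each frame
    (inclusive endpoints; at 0.1-s resolution the endpoint weighting is
    negligible relative to frame durations >= 15 s).
    """
    t_s = t_min * 60.0
    out = np.empty(schedule.n_frames)
    for i, (s, e) in enumerate(zip(schedule.start_s, schedule.end_s)):
        lo = np.searchsorted(t_s, s - 1e-9, side="left")
        hi = np.searchsorted(t_s, e + 1e-9, side="right")
        if hi <= lo:
            raise ValueError("fine grid does not cover frame window")
        out[i] = values[lo:hi].mean()
    return out


def biexp_reference(amplitude: float, lambda1: float, lambda2: float):
    """Continuous bi-exponential reference curve A*(e^-l1 t - e^-l2 t), t in min.

    Requires lambda2 > lambda1 > 0 so the curve is non-negative with a washout
    tail governed by lambda1.
    """
    if not (lambda2 > lambda1 > 0):
        raise ValueError("require lambda2 > lambda1 > 0 (equal rates degenerate)")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")

    def c_r(t):
        t = np.asarray(t, dtype=float)
        return amplitude * (np.exp(-lambda1 * t) - np.exp(-lambda2 * t))

    return c_r


def biexp_frame_means(
    amplitude: float, lambda1: float, lambda2: float, schedule
) -> np.ndarray:
    """Frame means of the bi-exponential curve by its analytic antiderivative."""
    biexp_reference(amplitude, lambda1, lambda2)  # validate parameters
    t0 = schedule.start_s / 60.0
    t1 = schedule.end_s / 60.0

    def integral(a, b, lam):
        return (np.exp(-lam * a) - np.exp(-lam * b)) / lam

    dur = t1 - t0
    return amplitude * (integral(t0, t1, lambda1) - integral(t0, t1, lambda2)) / dur
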