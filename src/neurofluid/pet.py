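"""Amyloid-PET quantification: late-frame SUVr and SRTM/SRTM2 binding potential.

Static route: duration-weighted average of the late frames (default 50-70 min
window), robust (trimmed-mean) region statistics, and the ratio of the global
mask to cerebellar grey matter (SUVr). Dose and body-weight normalisation are
omitted because they cancel in the ratio.

Dynamic route: basis-function SRTM. For each candidate efflux constant
theta = k2a, the model

    C_T ~ R1 * C_R + phi * [C_R (x) exp(-theta t)]

is linear; theta is selected on a logarithmic grid by residual sum of squares
and then polished by a bounded 1-D search between the neighbouring grid
points, so parameter recovery is not limited by the grid spacing. SRTM2 fixes
the reference efflux constant k2' = k2/R1 to the median over voxels with
first-pass BP_ND above a threshold (default 0.1) and refits a single scale
parameter per candidate theta; BP_ND = k2'/theta - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import DynamicImage, FrameSchedule, LabelAtlas
from .kinetics import (
    DEFAULT_FINE_DT_S,
    expconv,
    fine_time_grid,
    frame_average_curve,
)

__all__ = [
    "SRTMFit",
    "default_theta_grid",
    "frame_average",
    "trimmed_mean",
    "suvr_global",
    "fit_srtm",
    "fit_srtm2_map",
    "SRTMWorkspace",
]

DEFAULT_BP_THRESHOLD = 0.1


def default_theta_grid(n: int = 64, lo: float = 0.006, hi: float = 0.6) -> np.ndarray:
    """Logarithmic k2a candidate grid in 1/min."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class SRTMFit:
    r1: float
    k2: float
    bp_nd: float
    k2a: float
    k2prime: float
    rss: float
    on_grid_boundary: bool = False


# ---------------------------------------------------------------------------
# static quantification


def frame_average(dynamic: DynamicImage, window_start_s: float, window_end_s: float) -> np.ndarray:
    """Duration-weighted mean of the frames fully inside [start, end].

    The window must be tiled exactly by whole frames; a window that starts or
    ends inside a frame, or extends beyond the schedule, is rejected with the
    uncovered gap named.
    """
    sched = dynamic.schedule
    inside = (sched.start_s >= window_start_s - 1e-6) & (
        sched.end_s <= window_end_s + 1e-6
    )
    covered = sched.duration_s[inside].sum()
    if not math.isclose(covered, window_end_s - window_start_s, abs_tol=1e-6):
        raise ValueError(
            f"window [{window_start_s}, {window_end_s}] s is not tiled by whole "
            f"frames (frames cover {covered:g} s of it)"
        )
    w = sched.duration_s[inside]
    return np.tensordot(dynamic.data[..., inside], w / w.sum(), axes=([3], [0]))


def trimmed_mean(values, trim_fraction: float = 0.10) -> float:
    """Mean after discarding floor(trim_fraction * n) values from each tail."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("trimmed_mean of an empty collection")
    if not (0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = int(math.floor(trim_fraction * vals.size))
    vals = np.sort(vals)
    kept = vals[k : vals.size - k] if k else vals
    return float(kept.mean())


def suvr_global(
    static: np.ndarray,
    atlas: LabelAtlas,
    global_mask_label: int,
    cerebellar_gm_label: int,
    trim_fraction: float = 0.10,
) -> float:
    """Trimmed-mean global uptake over trimmed-mean cerebellar-GM uptake."""
    static = np.asarray(static, dtype=float)
    gmask = atlas.mask(global_mask_label)
    rmask = atlas.mask(cerebellar_gm_label)
    if not gmask.any() or not rmask.any():
        raise ValueError("global and reference labels must both be non-empty")
    ref = trimmed_mean(static[rmask], trim_fraction)
    if ref <= 0:
        raise ValueError("reference trimmed mean is non-positive")
    return trimmed_mean(static[gmask], trim_fraction) / ref


# ---------------------------------------------------------------------------
# SRTM fitting


class SRTMWorkspace:
    """Precomputed fine-grid reference curve and basis functions.

    Built once per (reference TAC, schedule, theta grid) and reused across
    voxels: the reference frame TAC is interpolated to the fine grid
    (anchored at zero activity at t=0 and the frame mid-times), and the
    frame-averaged convolution basis B_theta is cached for every grid theta.
    """

    def __init__(
        self,
        ref_tac: np.ndarray,
        schedule: FrameSchedule,
        theta_grid: np.ndarray | None = None,
        dt_s: float = DEFAULT_FINE_DT_S,
    ):
        self.schedule = schedule
        self.theta_grid = (
            np.asarray(theta_grid, dtype=float)
            if theta_grid is not None
            else default_theta_grid()
        )
        if np.any(self.theta_grid <= 0) or np.any(np.diff(self.theta_grid) <= 0):
            raise ValueError("theta grid must be positive and strictly increasing")
        ref_tac = np.asarray(ref_tac, dtype=float)
        if ref_tac.shape != (schedule.n_frames,):
            raise ValueError("reference TAC must have one value per frame")
        self.t = fine_time_grid(schedule.total_s, dt_s)
        # Reconstruct the fine-grid reference curve from its frame means:
        # start from midpoint interpolation (zero activity at t=0), then
        # iteratively nudge the knot values until the interpolant's own frame
        # means reproduce the measured ones (removes the curvature bias of
        # midpoint sampling over the short early frames).
        knots_min = np.concatenate([[0.0], schedule.mid_s / 60.0])
        knot_vals = np.concatenate([[0.0], ref_tac])
        for _ in range(12):
            fine = np.interp(self.t, knots_min, knot_vals)
            model_means = frame_average_curve(fine, self.t, schedule)
            err = ref_tac - model_means
            if np.max(np.abs(err)) < 1e-10 * max(np.max(np.abs(ref_tac)), 1e-30):
                break
            knot_vals[1:] += err
        self.ref_fine = np.clip(np.interp(self.t, knots_min, knot_vals), 0.0, None)
        self.ref_frames = frame_average_curve(self.ref_fine, self.t, schedule)
        self.basis = np.stack([self.basis_for(th) for th in self.theta_grid])
        # Gram pieces reused by the vectorised two-parameter grid solve
        self._rr = float(self.ref_frames @ self.ref_frames)
        self._rb = self.basis @ self.ref_frames
        self._bb = np.einsum("ij,ij->i", self.basis, self.basis)

    def basis_for(self, theta: float) -> np.ndarray:
        conv = expconv(theta, self.t, self.ref_fine)
        return frame_average_curve(conv, self.t, self.schedule)

    # -- two-parameter solve (R1, phi) for one theta ------------------------

    def _solve2(self, theta: float, y: np.ndarray):
        b = self.basis_for(theta)
        a = np.column_stack([self.ref_frames, b])
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        resid = y - a @ coef
        return coef, float(resid @ resid)

    def grid_rss2(self, y: np.ndarray):
        """RSS over the theta grid for the two-parameter model, closed form."""
        ry = float(self.ref_frames @ y)
        by = self.basis @ y
        det = self._rr * self._bb - self._rb**2
        safe = det > 1e-300
        r1 = np.where(safe, (ry * self._bb - by * self._rb) / np.where(safe, det, 1), 0)
        phi = np.where(safe, (self._rr * by - self._rb * ry) / np.where(safe, det, 1), 0)
        rss = (y @ y) - r1 * ry - phi * by
        return rss, r1, phi

    # -- one-parameter (SRTM2 second pass) ----------------------------------

    def design1(self, theta: float, k2prime: float) -> np.ndarray:
        return self.ref_frames + (k2prime - theta) * self.basis_for(theta)

    def _solve1(self, theta: float, k2prime: float, y: np.ndarray):
        x = self.design1(theta, k2prime)
        xx = float(x @ x)
        r1 = float(x @ y) / xx if xx > 0 else 0.0
        resid = y - r1 * x
        return r1, float(resid @ resid)


def _refine_theta(rss_fn, theta_grid, i_best):
    """Bounded scalar polish of theta between the neighbouring grid points."""
    lo = theta_grid[max(i_best - 1, 0)]
    hi = theta_grid[min(i_best + 1, len(theta_grid) - 1)]
    if hi <= lo:
        return float(theta_grid[i_best])
    res = minimize_scalar(
        rss_fn, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    return float(res.x)


def fit_srtm(
    target_tac: np.ndarray,
    ref_tac: np.ndarray | None = None,
    schedule: FrameSchedule | None = None,
    theta_grid: np.ndarray | None = None,
    refine: bool = True,
    workspace: SRTMWorkspace | None = None,
) -> SRTMFit:
    """Fit (R1, k2, BP_ND) to one target TAC by basis-function SRTM.

    Either a prebuilt ``workspace`` or (``ref_tac``, ``schedule``) must be
    given. A best theta on the grid boundary is flagged on the result rather
    than rejected (the grid was too narrow for this voxel).
    """
    ws = workspace or SRTMWorkspace(ref_tac, schedule, theta_grid)
    y = np.asarray(target_tac, dtype=float)
    if y.shape != (ws.schedule.n_frames,):
        raise ValueError("target TAC must have one value per frame")
    rss, _, _ = ws.grid_rss2(y)
    i = int(np.argmin(rss))
    boundary = i in (0, len(ws.theta_grid) - 1)
    theta = float(ws.theta_grid[i])
    if refine and not boundary:
        theta = _refine_theta(lambda th: ws._solve2(th, y)[1], ws.theta_grid, i)
    (r1, phi), rss_best = ws._solve2(theta, y)
    k2 = phi + r1 * theta
    bp = k2 / theta - 1.0
    return SRTMFit(
        r1=float(r1),
        k2=float(k2),
        bp_nd=float(bp),
        k2a=theta,
        k2prime=float(k2 / r1) if r1 != 0 else float("nan"),
        rss=rss_best,
        on_grid_boundary=boundary,
    )


def _fit_srtm2_single(ws: SRTMWorkspace, y: np.ndarray, k2prime: float, refine: bool):
    rss = np.empty(len(ws.theta_grid))
    for j, th in enumerate(ws.theta_grid):
        x = ws.ref_frames + (k2prime - th) * ws.basis[j]
        xx = x @ x
        r1 = (x @ y) / xx if xx > 0 else 0.0
        rss[j] = y @ y - r1 * (x @ y)
    i = int(np.argmin(rss))
    theta = float(ws.theta_grid[i])
    if refine and 0 < i < len(ws.theta_grid) - 1:
        theta = _refine_theta(
            lambda th: ws._solve1(th, k2prime, y)[1], ws.theta_grid, i
        )
    r1, rss_best = ws._solve1(theta, k2prime, y)
    return r1, theta, rss_best


@dataclass
class SRTM2MapResult:
    bp_map: np.ndarray
    r1_map: np.ndarray
    k2prime_fixed: float
    n_voxels_median: int
    n_boundary_hits: int


def fit_srtm2_map(
    dynamic: DynamicImage,
    ref_tac: np.ndarray,
    brain_mask: np.ndarray,
    bp_threshold: float = DEFAULT_BP_THRESHOLD,
    theta_grid: np.ndarray | None = None,
    refine: bool = True,
) -> SRTM2MapResult:
    """Two-step SRTM2 parametric mapping over a brain mask.

    Step 1 fits full SRTM per voxel; the reference efflux constant k2' is
    fixed to the median of per-voxel k2' over voxels with step-1 BP_ND above
    ``bp_threshold``. Step 2 refits each voxel with k2' fixed, yielding the
    final BP_ND and R1 maps. Voxels sharing an identical TAC (piecewise-
    constant phantoms) are fitted once and broadcast.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    ws = SRTMWorkspace(ref_tac, dynamic.schedule, theta_grid)
    tacs = dynamic.data[mask]  # (n_vox, n_frames)
    uniq, inverse = np.unique(tacs, axis=0, return_inverse=True)

    step1 = [fit_srtm(y, workspace=ws, refine=refine) for y in uniq]
    bp1 = np.array([f.bp_nd for f in step1])[inverse]
    k2p1 = np.array([f.k2prime for f in step1])[inverse]
    n_boundary = int(sum(f.on_grid_boundary for f in step1))

    use = bp1 > bp_threshold
    if not use.any():
        raise ValueError(
            f"no voxel has step-1 BP_ND > {bp_threshold}; k2' is undefined"
        )
    k2prime_fixed = float(np.median(k2p1[use]))

    step2 = [_fit_srtm2_single(ws, y, k2prime_fixed, refine) for y in uniq]
    r1_2 = np.array([s[0] for s in step2])[inverse]
    theta2 = np.array([s[1] for s in step2])[inverse]
    # k2 = R1 * k2' and theta = k2a, so BP_ND = R1 * k2' / theta - 1
    bp2 = r1_2 * k2prime_fixed / theta2 - 1.0

    bp_map = np.full(dynamic.data.shape[:3], np.nan)
    r1_map = np.full(dynamic.data.shape[:3], np.nan)
    bp_map[mask] = bp2
    r1_map[mask] = r1_2
    return SRTM2MapResult(
        bp_map=bp_map,
        r1_map=r1_map,
        k2prime_fixed=k2prime_fixed,
        n_voxels_median=int(use.sum()),
        n_boundary_hits=n_boundary,
    )
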