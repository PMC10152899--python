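"""Net CSF flow through the aqueduct from cardiac-gated phase-contrast MRI.

The acquired phase maps linearly to through-plane velocity, v = VENC * phi / pi
(cm/s). Velocities beyond VENC alias by +/- 2*VENC; unaliasing shifts samples
toward the per-phase ROI spatial median, which is robust to a wrapped
minority. The net flow is the flux waveform integrated over one cardiac cycle
times the heart rate — equivalently the mean flux times 60 — so it is
invariant to the heart rate itself for a fixed per-phase flux series.

Sign convention: positive velocity is cranial-to-caudal, so negative net flow
denotes anterograde (caudal-to-cranial) movement; ``flip_sign`` inverts it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCSeries", "FlowResult", "phase_to_velocity", "unalias", "net_flow"]


@dataclass
class PCSeries:
    """Cardiac-phase-resolved phase (radians) and magnitude grids.

    Axis 3 is the cardiac phase; phase values lie in (-pi, pi].
    """

    phase: np.ndarray
    magnitude: np.ndarray
    venc_cm_s: float
    voxel_size_mm: tuple
    heart_rate_bpm: float
    true_net_flow_ml_min: float | None = None

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.phase.ndim != 4 or self.phase.shape[3] < 2:
            raise ValueError("phase must be 4-D with >= 2 cardiac phases")
        if self.phase.shape != self.magnitude.shape:
            raise ValueError("phase and magnitude geometry must match")
        if np.any(self.phase > np.pi + 1e-9) or np.any(self.phase <= -np.pi - 1e-9):
            raise ValueError("phase values must lie in (-pi, pi]")
        if self.venc_cm_s <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("VENC and heart rate must be positive")

    @property
    def n_phases(self) -> int:
        return self.phase.shape[3]


@dataclass(frozen=True)
class FlowResult:
    flux_ml_s: np.ndarray  # per cardiac phase
    stroke_volume_ml: float
    net_flow_ml_min: float
    heart_rate_bpm: float
    sign_convention: str = "positive=cranial-to-caudal"
    n_unaliased: int = 0


def phase_to_velocity(pc: PCSeries) -> np.ndarray:
    """Velocity grids in cm/s: v = VENC * phi / pi, so |v| <= VENC before unaliasing."""
    return pc.venc_cm_s * pc.phase / np.pi


def unalias(velocity: np.ndarray, venc_cm_s: float):
    """Correct single-wrap aliasing within an ROI velocity series.

    ``velocity`` has cardiac phase on the last axis; leading axes index ROI
    voxels. Any sample deviating from the ROI spatial median at its cardiac
    phase by more than VENC is shifted by 2*VENC toward the median (exactly
    one shift). Returns (corrected, n_corrected); raises if a shifted sample
    still deviates by more than VENC (beyond the single-wrap regime).
    """
    v = np.asarray(velocity, dtype=float)
    if v.size == 0:
        raise ValueError("empty ROI")
    med = np.median(v.reshape(-1, v.shape[-1]), axis=0)
    dev = v - med
    wrapped = np.abs(dev) > venc_cm_s
    corrected = np.where(wrapped, v - np.sign(dev) * 2.0 * venc_cm_s, v)
    if np.any(np.abs(corrected - med) > venc_cm_s + 1e-9):
        raise ValueError(
            "residual deviation exceeds VENC after one wrap; velocities are "
            "beyond the single-wrap regime"
        )
    return corrected, int(np.count_nonzero(wrapped))


def net_flow(
    velocity: np.ndarray,
    roi_mask: np.ndarray,
    voxel_size_mm,
    heart_rate_bpm: float,
    apply_unalias: bool = True,
    venc_cm_s: float | None = None,
    flip_sign: bool = False,
) -> FlowResult:
    """Integrate the ROI flux waveform over a cardiac cycle.

    flux_k = sum_{voxels in ROI} v * A_voxel (ml/s) with A_voxel the in-plane
    voxel area; stroke volume = sum_k flux_k * (cycle / n_phases); net flow =
    stroke volume * heart rate = mean flux * 60.
    """
    v = np.asarray(velocity, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be positive")
    roi_v = v[mask]  # (n_voxels, n_phases)
    n_corr = 0
    if apply_unalias:
        if venc_cm_s is None:
            raise ValueError("venc_cm_s required when unaliasing is enabled")
        roi_v, n_corr = unalias(roi_v, venc_cm_s)
    if flip_sign:
        roi_v = -roi_v
    area_cm2 = (voxel_size_mm[0] * voxel_size_mm[1]) / 100.0
    flux = roi_v.sum(axis=0) * area_cm2  # cm/s * cm^2 = ml/s
    n_phases = flux.size
    cycle_s = 60.0 / heart_rate_bpm
    stroke = float(flux.sum() * cycle_s / n_phases)
    net = stroke * heart_rate_bpm  # == mean flux * 60
    return FlowResult(
        flux_ml_s=flux,
        stroke_volume_ml=stroke,
        net_flow_ml_min=net,
        heart_rate_bpm=heart_rate_bpm,
        sign_convention=(
            "positive=caudal-to-cranial" if flip_sign else "positive=cranial-to-caudal"
        ),
        n_unaliased=n_corr,
    )
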