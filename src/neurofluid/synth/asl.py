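"""ASL forward simulation: difference signals that invert to a known CBF."""

from __future__ import annotations

import numpy as np

from ..asl import ASLParams, ASLSeries
from ..core import LabelAtlas

__all__ = ["simulate_asl"]


def simulate_asl(
    atlas: LabelAtlas,
    cbf_truth: dict,
    acq: ASLParams,
    n_pairs: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
    m0_value: float = 1000.0,
    baseline_fraction: float = 0.02,
) -> ASLSeries:
    """Control/label series whose noiseless quantification equals ``cbf_truth``.

    The per-label control-label difference is the closed-form inversion of the
    single-compartment CBF equation at each slice's effective post-label
    delay; the static tissue baseline is ``baseline_fraction * m0_value`` and
    Gaussian noise of SD ``noise_sd`` is added independently per volume.
    Labels absent from ``cbf_truth`` (and background) get zero perfusion.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    shape = atlas.data.shape
    m0 = np.full(shape, float(m0_value))

    t1b = acq.blood_t1_ms
    slices = np.arange(shape[2])
    pld_slice = acq.post_label_delay_ms + slices * acq.slice_time_inc_ms
    decay = np.exp(pld_slice / t1b)[np.newaxis, np.newaxis, :]
    denom_factor = (
        2.0
        * acq.labeling_efficiency
        * (t1b / 1000.0)
        * m0_value
        * (1.0 - np.exp(-acq.label_duration_ms / t1b))
    )

    cbf_map = np.zeros(shape)
    for lab, cbf in cbf_truth.items():
        cbf_map[atlas.data == int(lab)] = float(cbf)
    dm = cbf_map * denom_factor / (6000.0 * acq.partition_coefficient * decay)

    base = baseline_fraction * m0_value
    control = base + dm
    label = np.full(shape, base)
    vols = np.empty(shape + (2 * n_pairs,))
    vols[..., 0::2] = control[..., np.newaxis]
    vols[..., 1::2] = label[..., np.newaxis]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vols = vols + rng.standard_normal(vols.shape) * noise_sd
    return ASLSeries(vols, m0, acq, control_first=True, voxel_size_mm=atlas.voxel_size_mm)
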