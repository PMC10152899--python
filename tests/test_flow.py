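"""Phase-contrast velocity mapping, unaliasing and net-flow integration."""

import numpy as np
import pytest

from neurofluid.flow import PCSeries, net_flow, phase_to_velocity, unalias
from neurofluid.synth.flow import simulate_phase_contrast

VOX = (0.59, 0.59, 4.0)


def _roi(n=3, grid=16):
    roi = np.zeros((grid, grid, 1), dtype=bool)
    lo = (grid - n) // 2
    roi[lo : lo + n, lo : lo + n, 0] = True
    return roi


def _pc(phase, venc=12.0, hr=60.0):
    return PCSeries(phase, np.ones_like(phase), venc, VOX, hr)


class TestPhaseToVelocity:
    @pytest.mark.parametrize(
        "phi,expected",
        [(0.0, 0.0), (np.pi, 12.0), (-np.pi / 2, -6.0)],
    )
    def test_linear_map(self, phi, expected):
        phase = np.full((2, 2, 1, 2), phi)
        v = phase_to_velocity(_pc(phase))
        np.testing.assert_allclose(v, expected, atol=1e-12)

    def test_phase_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="pi"):
            _pc(np.full((2, 2, 1, 2), 4.0))


class TestUnalias:
    def test_no_deviation_identity(self):
        v = np.full((5, 12), 3.0)
        out, n = unalias(v, 12.0)
        np.testing.assert_array_equal(out, v)
        assert n == 0

    def test_single_wrap_toward_median(self):
        # median 10, wrapped sample -11, venc 12 -> restored to 13
        v = np.full((5, 1), 10.0)
        v[2, 0] = -11.0
        out, n = unalias(v, 12.0)
        assert n == 1
        assert out[2, 0] == pytest.approx(13.0)

    def test_counts_every_wrapped_sample(self, rng):
        # 3 of 10 samples wrap; exhaustive per-sample deviation oracle
        truth = rng.uniform(-2.0, 2.0, (10, 1))
        v = truth.copy()
        wrapped_idx = [1, 4, 8]
        v[wrapped_idx, 0] = truth[wrapped_idx, 0] + 24.0  # one wrap up
        med = np.median(v, axis=0)
        expected = int(np.sum(np.abs(v - med) > 12.0))
        out, n = unalias(v, 12.0)
        assert n == expected == 3
        np.testing.assert_allclose(out, truth, atol=1e-12)

    def test_beyond_single_wrap_raises(self):
        v = np.zeros((5, 1))
        v[0, 0] = 40.0  # still beyond venc of the median after one 2*venc shift
        with pytest.raises(ValueError, match="single-wrap"):
            unalias(v, 12.0)


class TestNetFlow:
    def test_zero_velocity_zero_flow(self):
        roi = _roi()
        v = np.zeros(roi.shape + (12,))
        res = net_flow(v, roi, VOX, 70.0, apply_unalias=False)
        assert res.net_flow_ml_min == 0.0
        assert res.stroke_volume_ml == 0.0

    def test_steady_flow_hand_oracle(self):
        # 10 voxels of 0.59 x 0.59 mm at a steady 2 cm/s
        roi = np.zeros((8, 8, 1), dtype=bool)
        roi.ravel()[:10] = True
        v = np.where(roi[..., None], 2.0, 0.0) * np.ones((1, 1, 1, 12))
        area_cm2 = 10 * 0.59 * 0.59 / 100.0
        for hr in (50.0, 80.0):
            res = net_flow(v, roi, VOX, hr, apply_unalias=False)
            np.testing.assert_allclose(res.flux_ml_s, 2.0 * area_cm2)
            assert res.flux_ml_s[0] == pytest.approx(0.0696, abs=2e-4)
            assert res.net_flow_ml_min == pytest.approx(2.0 * area_cm2 * 60.0)
            assert res.net_flow_ml_min == pytest.approx(4.18, abs=0.01)
            # net flow = stroke volume x heart rate by construction
            assert res.net_flow_ml_min == pytest.approx(res.stroke_volume_ml * hr)

    def test_zero_mean_sinusoid_gives_zero_net_flow(self):
        roi = _roi()
        wave = np.sin(2 * np.pi * np.arange(12) / 12)
        v = np.zeros(roi.shape + (12,))
        v[roi] = 3.0 * wave
        res = net_flow(v, roi, VOX, 66.0, apply_unalias=False)
        assert abs(res.net_flow_ml_min) < 1e-12

    def test_net_flow_invariant_to_heart_rate(self, rng):
        roi = _roi()
        v = np.zeros(roi.shape + (12,))
        v[roi] = rng.uniform(-5, 5, (roi.sum(), 12))
        flows = [
            net_flow(v, roi, VOX, hr, apply_unalias=False).net_flow_ml_min
            for hr in (45.0, 60.0, 95.0)
        ]
        np.testing.assert_allclose(flows, flows[0], rtol=1e-12)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty"):
            net_flow(np.zeros((4, 4, 1, 12)), np.zeros((4, 4, 1), bool), VOX, 60.0)


class TestSimulationRoundTrip:
    def test_zero_waveform_is_all_zero(self):
        pc = simulate_phase_contrast(np.zeros(12), _roi(), 12.0, VOX, 60.0)
        assert not pc.phase.any()
        assert pc.true_net_flow_ml_min == 0.0

    def test_wrap_by_two_venc(self):
        # uniform 13 cm/s against VENC 12 stores a phase meaning -11 cm/s
        roi = _roi()
        area = roi.sum() * VOX[0] * VOX[1] / 100.0
        q = np.full(12, 13.0 * area)
        pc = simulate_phase_contrast(q, roi, 12.0, VOX, 60.0, wrap=True)
        v = phase_to_velocity(pc)
        np.testing.assert_allclose(v[roi], -11.0, atol=1e-9)

    def test_sinusoid_with_mean_flux_converts_to_ml_min(self):
        q = 0.01 + 0.02 * np.sin(2 * np.pi * np.arange(12) / 12)
        pc = simulate_phase_contrast(q, _roi(), 12.0, VOX, 60.0)
        assert pc.true_net_flow_ml_min == pytest.approx(0.6)

    def test_unwrapped_round_trip_and_roi_dilation_invariance(self):
        roi = _roi()
        area = roi.sum() * VOX[0] * VOX[1] / 100.0
        q = 0.01 + 5.0 * area * np.sin(2 * np.pi * np.arange(12) / 12)
        pc = simulate_phase_contrast(q, roi, 12.0, VOX, 72.0, profile="parabolic")
        v = phase_to_velocity(pc)
        res = net_flow(v, roi, VOX, 72.0, apply_unalias=True, venc_cm_s=12.0)
        assert res.net_flow_ml_min == pytest.approx(pc.true_net_flow_ml_min, rel=1e-9)
        assert res.n_unaliased == 0
        dilated = _roi(7)
        res2 = net_flow(v, dilated, VOX, 72.0, apply_unalias=True, venc_cm_s=12.0)
        assert res2.net_flow_ml_min == res.net_flow_ml_min  # exactly

    def test_wrapped_round_trip_recovers_truth(self):
        roi = _roi()
        area = roi.sum() * VOX[0] * VOX[1] / 100.0
        q = 0.01 + 9.0 * area * np.sin(2 * np.pi * np.arange(12) / 12)
        pc = simulate_phase_contrast(
            q, roi, 12.0, VOX, 72.0, wrap=True, profile="parabolic"
        )
        v = phase_to_velocity(pc)
        res = net_flow(v, roi, VOX, 72.0, apply_unalias=True, venc_cm_s=12.0)
        assert res.n_unaliased > 0
        assert res.net_flow_ml_min == pytest.approx(pc.true_net_flow_ml_min, rel=0.02)

    def test_velocity_beyond_two_venc_rejected(self):
        roi = _roi()
        area = roi.sum() * VOX[0] * VOX[1] / 100.0
        q = np.full(12, 25.0 * area)
        with pytest.raises(ValueError, match="2\\*VENC"):
            simulate_phase_contrast(q, roi, 12.0, VOX, 60.0, wrap=True)
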