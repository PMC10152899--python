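"""SRTM / SRTM2 parameter recovery on simulated phantoms."""

import numpy as np
import pytest

from neurofluid.pet import default_theta_grid, fit_srtm, fit_srtm2_map
from neurofluid.synth.pet import KineticGroundTruth, simulate_dynamic_pet


def _simulate_pair(atlas, schedule, r1, k2, bp):
    truth = KineticGroundTruth({1: (1.0, 0.2, 0.0), 2: (r1, k2, bp)}, 1)
    dyn = simulate_dynamic_pet(atlas, truth, schedule)
    return dyn.data[atlas.mask(2)][0], dyn.data[atlas.mask(1)][0]


class TestFitSRTM:
    def test_target_equal_reference_is_nondisplaceable(self, two_region_atlas, pib_schedule):
        tac, ref = _simulate_pair(two_region_atlas, pib_schedule, 1.0, 0.2, 0.0)
        fit = fit_srtm(ref, ref, pib_schedule)
        assert fit.r1 == pytest.approx(1.0, abs=1e-3)
        assert abs(fit.bp_nd) < 1e-2

    @pytest.mark.parametrize("bp", [0.1, 0.5, 1.0])
    @pytest.mark.parametrize("r1", [0.8, 1.2])
    def test_noiseless_recovery_within_one_percent(
        self, two_region_atlas, pib_schedule, bp, r1
    ):
        k2 = 0.15
        tac, ref = _simulate_pair(two_region_atlas, pib_schedule, r1, k2, bp)
        fit = fit_srtm(tac, ref, pib_schedule)
        assert fit.r1 == pytest.approx(r1, rel=0.01)
        assert fit.k2 == pytest.approx(k2, rel=0.01)
        assert fit.bp_nd == pytest.approx(bp, rel=0.01)
        assert not fit.on_grid_boundary

    def test_scaling_behaviour_of_fitted_parameters(
        self, two_region_atlas, pib_schedule
    ):
        # scaling the target alone scales delivery and the distribution
        # volume ratio (BP_ND + 1) by the same factor; scaling target and
        # reference together is a pure unit change and leaves everything
        # dimensionless untouched
        tac, ref = _simulate_pair(two_region_atlas, pib_schedule, 1.1, 0.15, 0.4)
        base = fit_srtm(tac, ref, pib_schedule)
        scaled = fit_srtm(3.0 * tac, ref, pib_schedule)
        assert scaled.r1 == pytest.approx(3.0 * base.r1, rel=1e-6)
        assert scaled.bp_nd + 1 == pytest.approx(3.0 * (base.bp_nd + 1), rel=1e-6)
        both = fit_srtm(3.0 * tac, 3.0 * ref, pib_schedule)
        assert both.r1 == pytest.approx(base.r1, rel=1e-6)
        assert both.bp_nd == pytest.approx(base.bp_nd, rel=1e-6)

    def test_fitted_binding_monotone_in_true_binding(
        self, two_region_atlas, pib_schedule
    ):
        fits = []
        for bp in (0.2, 0.4, 0.8, 1.2):
            tac, ref = _simulate_pair(two_region_atlas, pib_schedule, 1.0, 0.15, bp)
            fits.append(fit_srtm(tac, ref, pib_schedule).bp_nd)
        assert np.all(np.diff(fits) > 0)

    def test_boundary_theta_is_flagged(self, two_region_atlas, pib_schedule):
        tac, ref = _simulate_pair(two_region_atlas, pib_schedule, 1.0, 0.15, 0.5)
        narrow = default_theta_grid(8, 0.3, 0.6)  # truth k2a = 0.1 below the grid
        fit = fit_srtm(tac, ref, pib_schedule, theta_grid=narrow)
        assert fit.on_grid_boundary


class TestSRTM2Map:
    def test_shared_k2prime_phantom_recovery(self, two_region_atlas, pib_schedule):
        # all regions share k2' = 0.18/min; both the fixed k2' and the final
        # binding map must land within 1%
        truth = KineticGroundTruth(
            {1: (1.0, 0.18, 0.0), 2: (1.2, 1.2 * 0.18, 0.6)}, 1
        )
        dyn = simulate_dynamic_pet(two_region_atlas, truth, pib_schedule)
        ref = dyn.data[two_region_atlas.mask(1)][0]
        res = fit_srtm2_map(dyn, ref, two_region_atlas.data > 0)
        assert res.k2prime_fixed == pytest.approx(0.18, rel=0.01)
        bp = res.bp_map[two_region_atlas.mask(2)]
        np.testing.assert_allclose(bp, 0.6, rtol=0.01)

    def test_step2_matches_step1_when_k2prime_already_shared(
        self, two_region_atlas, pib_schedule
    ):
        truth = KineticGroundTruth(
            {1: (1.0, 0.18, 0.0), 2: (0.9, 0.9 * 0.18, 0.8)}, 1
        )
        dyn = simulate_dynamic_pet(two_region_atlas, truth, pib_schedule)
        ref = dyn.data[two_region_atlas.mask(1)][0]
        step1 = fit_srtm(dyn.data[two_region_atlas.mask(2)][0], ref, pib_schedule)
        res = fit_srtm2_map(dyn, ref, two_region_atlas.data > 0)
        bp2 = res.bp_map[two_region_atlas.mask(2)][0]
        assert bp2 == pytest.approx(step1.bp_nd, rel=5e-3)

    def test_reference_voxels_excluded_from_median_by_threshold(
        self, two_region_atlas, pib_schedule
    ):
        truth = KineticGroundTruth(
            {1: (1.0, 0.18, 0.0), 2: (1.0, 0.18, 0.9)}, 1
        )
        dyn = simulate_dynamic_pet(two_region_atlas, truth, pib_schedule)
        ref = dyn.data[two_region_atlas.mask(1)][0]
        res = fit_srtm2_map(dyn, ref, two_region_atlas.data > 0, bp_threshold=0.1)
        # only target voxels pass BP > 0.1
        assert res.n_voxels_median == int(two_region_atlas.mask(2).sum())

    def test_no_voxel_above_threshold_raises(self, two_region_atlas, pib_schedule):
        truth = KineticGroundTruth(
            {1: (1.0, 0.18, 0.0), 2: (1.0, 0.18, 0.0)}, 1
        )
        dyn = simulate_dynamic_pet(two_region_atlas, truth, pib_schedule)
        ref = dyn.data[two_region_atlas.mask(1)][0]
        with pytest.raises(ValueError, match="k2'"):
            fit_srtm2_map(dyn, ref, two_region_atlas.data > 0)

    def test_dvr_is_binding_plus_one(self, two_region_atlas, pib_schedule):
        truth = KineticGroundTruth(
            {1: (1.0, 0.18, 0.0), 2: (1.0, 0.18, 0.5)}, 1
        )
        dyn = simulate_dynamic_pet(two_region_atlas, truth, pib_schedule)
        ref = dyn.data[two_region_atlas.mask(1)][0]
        res = fit_srtm2_map(dyn, ref, two_region_atlas.data > 0)
        dvr = res.bp_map + 1.0
        assert np.nanmean(dvr[two_region_atlas.mask(2)]) == pytest.approx(1.5, rel=0.01)
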