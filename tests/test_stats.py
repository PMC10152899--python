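"""Rank statistics against hand oracles and established implementations."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, spearmanr

from neurofluid.stats import (
    anderson_darling,
    bh_fdr,
    partial_spearman,
    spearman,
)


def _ad_oracle(values):
    """Direct order-statistic evaluation of the normality A*^2."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    u = norm.cdf((x - x.mean()) / x.std(ddof=1))
    s = 0.0
    for i in range(1, n + 1):
        s += (2 * i - 1) * (math.log(u[i - 1]) + math.log(1 - u[n - i]))
    a2 = -n - s / n
    return a2 * (1 + 0.75 / n + 2.25 / n**2)


class TestAndersonDarling:
    def test_arithmetic_ramp_matches_oracle(self):
        x = np.arange(1.0, 21.0)
        a2, p = anderson_darling(x)
        assert a2 == pytest.approx(_ad_oracle(x), abs=1e-10)

    def test_duplicated_sample_matches_oracle(self):
        x = np.arange(1.0, 21.0)
        doubled = np.concatenate([x, x])
        a2, _ = anderson_darling(doubled)
        assert a2 == pytest.approx(_ad_oracle(doubled), abs=1e-10)

    def test_matches_statsmodels_p_value(self, rng):
        from statsmodels.stats.diagnostic import normal_ad

        x = rng.normal(size=37)
        a2, p = anderson_darling(x)
        sm_a2, sm_p = normal_ad(x)
        assert p == pytest.approx(sm_p, rel=1e-6)
        # statsmodels reports the unadjusted statistic
        n = x.size
        assert a2 == pytest.approx(sm_a2 * (1 + 0.75 / n + 2.25 / n**2), rel=1e-9)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant|variance"):
            anderson_darling([2.0] * 10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            anderson_darling([1.0, 2.0, 3.0])


class TestSpearman:
    def test_strictly_monotone_is_perfect(self):
        x = np.arange(10.0)
        res = spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_four_point_example(self):
        # d = (1,2,3,4) vs (2,1,4,3): sum d^2 = 4, rho = 1 - 6*4/(4*15) = 0.6
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)
        assert res.n == 4

    def test_exact_permutation_p_at_n4(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        res = spearman(x, y)
        rho_obs = 0.6
        count = 0
        for perm in permutations([1, 2, 3, 4]):
            d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4], perm))
            rho = 1 - 6 * d2 / (4 * 15)
            if abs(rho) >= rho_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / 24)

    def test_missing_pairs_dropped(self):
        x = [1, 2, 3, 4, 5, np.nan, 7, 8, 9, 10]
        y = [1, 2, 3, 4, 5, 6, 7, 8, np.nan, 10]
        res = spearman(x, y)
        assert res.n == 8
        assert res.rho == pytest.approx(1.0)

    def test_matches_scipy_on_continuous_data(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman(x, y)
        sp = spearmanr(x, y)
        assert res.rho == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, 3 * y + 2).rho == pytest.approx(base, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])

    def test_permutation_and_t_approximation_agree_on_strong_effects(self):
        # rejection at alpha = 0.05 coincides for |rho| >= 0.9, n <= 7
        from neurofluid.stats import _t_approx_p

        datasets = []
        for n in (5, 6, 7):
            x = list(range(n))
            datasets.append((x, x))  # rho = 1
            datasets.append((x, x[::-1]))  # rho = -1
        for n in (6, 7):
            x = list(range(n))
            y = x.copy()
            y[0], y[1] = y[1], y[0]  # one adjacent swap keeps |rho| >= 0.9
            assert abs(spearman(x, y).rho) >= 0.9
            datasets.append((x, y))
        for x, y in datasets:
            res = spearman(x, y)
            p_t = _t_approx_p(res.rho, res.n - 2)
            assert (res.p_value < 0.05) == (p_t < 0.05), (x, y, res.p_value, p_t)


class TestPartialSpearman:
    def test_empty_covariates_reduce_to_spearman(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = partial_spearman(x, y, [])
        b = spearman(x, y)
        assert a.rho == pytest.approx(b.rho)

    def test_identical_variables_give_unity(self, rng):
        x = rng.normal(size=25)
        z = rng.normal(size=25)
        res = partial_spearman(x, x, [z])
        assert res.rho == pytest.approx(1.0)

    def test_shared_covariate_explains_association(self):
        rng = np.random.default_rng(99)
        z = rng.normal(size=200)
        x = z + 0.5 * rng.normal(size=200)
        y = z + 0.5 * rng.normal(size=200)
        assert abs(spearman(x, y).rho) > 0.5  # raw association is strong
        res = partial_spearman(x, y, [z])
        assert abs(res.rho) < 0.15

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        df = pd.DataFrame(
            {
                "x": rng.normal(size=40),
                "y": rng.normal(size=40),
                "z": rng.normal(size=40),
                "s": rng.integers(0, 2, size=40),
            }
        )
        res = partial_spearman(df.x, df.y, [df.z, df.s])
        ref = pg.partial_corr(df, x="x", y="y", covar=["z", "s"], method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=0.02)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=0.02)

    def test_collinear_covariates_rejected(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(x, y, [z, 2 * z])


class TestBHFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_identical_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_subregion_family_hand_oracle(self):
        # step-up by hand: sorted (0.002, 0.010, 0.197, 0.653) ->
        # (0.008, 0.020, 0.2627, 0.653), restored to input order
        adjusted = bh_fdr([0.010, 0.002, 0.197, 0.653])
        np.testing.assert_allclose(
            adjusted, [0.020, 0.008, 0.197 * 4 / 3, 0.653], rtol=1e-12
        )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-4, 1.0, size=17)
        mine = bh_fdr(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, ref, rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_adjusted_at_least_raw_and_order_preserving(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
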