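"""Synthetic cohorts with a prescribed Spearman dependence.

(BP_ND, total PSD volume) pairs are drawn from a Gaussian copula whose latent
Pearson correlation is rho = 2*sin(pi * rho_S / 6), the exact inverse of the
bivariate-normal Spearman relation, so the population Spearman correlation
equals the target. Marginals are Gaussian, truncated at zero where the
quantity is physically non-negative (binding potential, volumes, perfusion);
truncation is applied through the truncated-normal quantile function, a
strictly monotone transform of the latent normal that leaves the Spearman
correlation untouched. Net CSF flow is left untruncated: retrograde
(cranial-to-caudal) flow is physiologically admissible and observed.

Default marginals follow the study cohort of older adults with amnestic MCI
or early Alzheimer's dementia: BP_ND 0.553 +/- 0.349, total PSD volume
11.85 +/- 2.16 cm^3, ChP perfusion 27.72 +/- 2.16 ml/100 g/min, net CSF flow
0.686 +/- 1.254 ml/min, ages 56-78, 10 of 23 male. Subregion volumes are the
fixed fractions of the total implied by the cohort subregion means
(prefrontal/frontal/parietal/occipital 0.41/5.45/3.34/2.66 cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

__all__ = ["CohortSpec", "simulate_cohort", "COHORT_COLUMNS"]

_SUBREGION_MEANS = np.array([0.41, 5.45, 3.34, 2.66])
DEFAULT_SUBREGION_FRACTIONS = tuple(_SUBREGION_MEANS / _SUBREGION_MEANS.sum())

COHORT_COLUMNS = [
    "subject_id",
    "age_years",
    "sex",
    "bp_nd",
    "suvr",
    "chp_perfusion_ml_100g_min",
    "net_csf_flow_ml_min",
    "psd_total_cm3",
    "psd_prefrontal_cm3",
    "psd_frontal_cm3",
    "psd_parietal_cm3",
    "psd_occipital_cm3",
    "gm_wm_volume_cm3",
    "icv_cm3",
]


@dataclass
class CohortSpec:
    n_subjects: int = 23
    bp_mean: float = 0.553
    bp_sd: float = 0.349
    psd_mean: float = 11.85
    psd_sd: float = 2.16
    perfusion_mean: float = 27.72
    perfusion_sd: float = 2.16
    flow_mean: float = 0.686
    flow_sd: float = 1.254
    target_spearman: float = 0.529
    subregion_fractions: tuple = DEFAULT_SUBREGION_FRACTIONS
    age_range: tuple = (56.0, 78.0)
    male_fraction: float = 10.0 / 23.0
    gm_wm_mean: float = 1050.0
    gm_wm_sd: float = 100.0
    icv_mean: float = 1450.0
    icv_sd: float = 130.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for sd in (self.bp_sd, self.psd_sd, self.perfusion_sd, self.flow_sd):
            if sd < 0:
                raise ValueError("marginal SDs must be >= 0")
        if not -1.0 <= self.target_spearman <= 1.0:
            raise ValueError("target Spearman must lie in [-1, 1]")
        fr = np.asarray(self.subregion_fractions, dtype=float)
        if fr.size != 4 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("subregion fractions must be 4 non-negative values summing to 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


def spearman_to_pearson(rho_s: float) -> float:
    """Latent bivariate-normal Pearson correlation for a target Spearman."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _truncated_at_zero(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.full_like(u, mean)
    a = (0.0 - mean) / sd
    return truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table; deterministic under spec.seed.

    Perfusion and net flow are independent of BP_ND (the null the cohort
    analysis should not reject); SUVr is an affine function of BP_ND plus
    measurement noise, mirroring the near-perfect static/dynamic agreement.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    rho = spearman_to_pearson(spec.target_spearman)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    u = norm.cdf(z)
    bp = _truncated_at_zero(u[:, 0], spec.bp_mean, spec.bp_sd)
    psd = _truncated_at_zero(u[:, 1], spec.psd_mean, spec.psd_sd)
    perfusion = _truncated_at_zero(
        norm.cdf(rng.standard_normal(n)), spec.perfusion_mean, spec.perfusion_sd
    )
    flow = spec.flow_mean + spec.flow_sd * rng.standard_normal(n)
    suvr = 1.0 + 1.45 * bp + 0.08 * rng.standard_normal(n)
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = (rng.random(n) < spec.male_fraction).astype(int)  # 1 = male
    fr = np.asarray(spec.subregion_fractions, dtype=float)
    sub = psd[:, np.newaxis] * fr[np.newaxis, :]

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age_years": np.round(age, 1),
            "sex": sex,
            "bp_nd": bp,
            "suvr": suvr,
            "chp_perfusion_ml_100g_min": perfusion,
            "net_csf_flow_ml_min": flow,
            "psd_total_cm3": psd,
            "psd_prefrontal_cm3": sub[:, 0],
            "psd_frontal_cm3": sub[:, 1],
            "psd_parietal_cm3": sub[:, 2],
            "psd_occipital_cm3": sub[:, 3],
            "gm_wm_volume_cm3": spec.gm_wm_mean + spec.gm_wm_sd * rng.standard_normal(n),
            "icv_cm3": spec.icv_mean + spec.icv_sd * rng.standard_normal(n),
        },
        columns=COHORT_COLUMNS,
    )
    return df
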