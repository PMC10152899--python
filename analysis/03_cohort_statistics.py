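#!/usr/bin/env python
"""Run the cohort statistics battery on the measured table.

Spearman correlations of global amyloid burden (BP_ND) against ChP
perfusion, net CSF flow and PSD volume; the four-subregion family with
BH-FDR; the atrophy control (GM+WM vs PSD, raw and ICV-adjusted); the
static/dynamic agreement (SUVr vs BP_ND + 1); partial-Spearman variants
covarying age and sex; and an Anderson-Darling normality screen.

Writes results/correlations.tsv and results/normality.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from neurofluid.pipeline import PipelineConfig, normality_table, run_cohort


def main():
    cfg = PipelineConfig()
    if len(sys.argv) > 1:
        cfg = PipelineConfig.from_yaml(sys.argv[1])
    measured = pd.read_csv(Path(cfg.out_dir) / "cohort_measured.tsv", sep="\t")
    results = run_cohort(measured)
    normality = normality_table(measured)
    out = Path(cfg.out_dir)
    results.to_csv(out / "correlations.tsv", sep="\t", index=False)
    normality.to_csv(out / "normality.tsv", sep="\t", index=False)

    pd.set_option("display.width", 160)
    print("correlation battery:")
    print(results.round(4).to_string(index=False))
    print("\nnormality screen (Anderson-Darling):")
    print(normality.round(4).to_string(index=False))
    sig = results[(results.covariates == "") & (results.p < 0.05)]
    print(
        f"\n{len(sig)} unadjusted test(s) below 0.05: "
        + ", ".join(f"{r.outcome}~{r.predictor}" for r in sig.itertuples())
    )


if __name__ == "__main__":
    main()
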