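#!/usr/bin/env python
"""Phantom round-trip validation of every quantification stage.

Delegates to scripts/acceptance.py's building blocks: SRTM/SRTM2 noiseless
recovery, GTM exactness, the closed-form CBF value, ASL and phase-contrast
round trips, Spearman null calibration and copula calibration. Writes
results/validation.json.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np

_spec = importlib.util.spec_from_file_location(
    "acceptance", Path(__file__).resolve().parents[1] / "scripts" / "acceptance.py"
)
acceptance = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(acceptance)


def main():
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    out = {}
    acceptance.fdr_of_subregion_pvalues(out)
    acceptance.srtm_recovery(out)
    acceptance.pvc_recovery(out, np.random.default_rng(seed))
    acceptance.asl_quantification(out)
    acceptance.flow_quantification(out, seed)
    acceptance.statistics_battery(out, seed)
    import json

    path = Path("results/validation.json")
    path.parent.mkdir(exist_ok=True)
    path.write_text(json.dumps(out, indent=1))
    for k, v in out.items():
        print(f"{k:42s} {v['value']:.6g}  (n={v['n']})")


if __name__ == "__main__":
    main()
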