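#!/usr/bin/env python
"""EWAS discovery and cross-cohort meta-analysis.

Per-probe regressions of T2D status (linear-on-binary, cohort 1) and of
ln-transformed HbA1c / HOMA-S / HOMA-B (both cohorts), inverse-variance
fixed-effects meta-analysis of the glycaemic traits, BH-FDR per trait, and
selection of the CpGs carried forward to MR.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _common import run_stages

cfg, out = run_stages(["ewas", "meta"])
lambdas = json.load(open(os.path.join(out, "ewas_lambdas.json")))
print("genomic inflation per scan:")
for name, lam in lambdas.items():
    print(f"  {name:28s} lambda = {lam:.3f}")
selected = [l.strip() for l in open(os.path.join(out, "selected_cpgs.txt")) if l.strip()]
print(f"CpGs selected for MR (FDR < {cfg['thresholds']['ewas_fdr']}): {selected}")
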