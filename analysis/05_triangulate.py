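#!/usr/bin/env python
"""Post hoc triangulation of the CpGs flagged causal.

Temporal stability of percent methylation between the two time points
(Bland-Altman), baseline methylation across tertiles of follow-up HbA1c
(Kruskal-Wallis) in the longitudinal subset, and cis/trans eQTM mapping
against blood, adipose and muscle expression with per-tissue FDR tiers.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from _common import run_stages

cfg, out = run_stages(["posthoc"])
ba = pd.read_csv(os.path.join(out, "bland_altman.tsv"), sep="\t")
stab = pd.read_csv(os.path.join(out, "stability.tsv"), sep="\t")
print("temporal drift of the causal CpGs (percentage points, t2 - t1):")
print(stab[stab["causal"]][["probe_id", "mean_beta_t1", "mean_beta_t2", "diff"]]
      .round(2).to_string(index=False))

tert = pd.read_csv(os.path.join(out, "tertiles.tsv"), sep="\t")
if len(tert):
    print("\nbaseline methylation by follow-up HbA1c tertile:")
    print(tert[["probe_id", "tertile", "n", "median_methylation_pct", "kw_p"]]
          .round(3).to_string(index=False))

for tissue in ("blood", "adipose", "muscle"):
    path = os.path.join(out, f"eqtm_{tissue}.tsv")
    if not os.path.exists(path):
        continue
    eqtm = pd.read_csv(path, sep="\t")
    hits = eqtm[eqtm["suggestive"]]
    if len(hits):
        print(f"\n{tissue} eQTMs at FDR < 0.2:")
        print(hits[["probe_id", "gene_id", "beta", "q", "relation", "significant"]]
              .round(4).to_string(index=False))
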