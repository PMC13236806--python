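#!/usr/bin/env python
"""Generate the synthetic two-cohort study.

Writes genotypes, methylation (two time points), phenotypes, tissue
expression and the ground-truth record under results/study/. The default
conditions: a population-based cohort (n=879, T2D prevalence 4.7%, three
recruitment sites), a clinic-based cohort supplying a glycaemic-trait EWAS
subset (n=332), a T2D-enriched meQTL subset (n=606, prevalence 46.2%), a
disjoint outcome-GWAS sample (n=4,000) and a small hepatocyte panel (n=56).
Two CpGs carry causal effects on T2D liability: log(0.76) and log(1.29) per
M-value unit.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(__file__))
from _common import load_cfg, run_stages

cfg, out = run_stages(["simulate"])
truth = json.load(open(os.path.join(out, "truth.json")))
print(f"wrote synthetic study to {out}")
print("causal CpG effects (log-odds per M-unit):")
for cpg, theta in truth["cpg_effects"].items():
    print(f"  {cpg}: theta = {theta:+.4f}  (OR = {2.718281828 ** theta:.2f})")
print("meQTL instruments per CpG:",
      {k: len(v) for k, v in truth["meqtl_effects"].items()})
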