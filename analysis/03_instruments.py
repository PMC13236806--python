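#!/usr/bin/env python
"""Build MR instruments from cis-meQTLs.

Genotype QC (missingness, MAF, exact HWE, INFO), additive cis-meQTL mapping
within +/-1 Mb of each selected CpG (blood n=606 and hepatocytes n=56
separately), greedy LD clumping at r^2 < 0.1, a confounder screen of the
clump indices (age, sex, BMI, waist, hip, smoking at p < 0.05), and
cumulative F statistics with the F > 10 admission bar.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from _common import run_stages

cfg, out = run_stages(["meqtl", "clump", "screen"])
for tissue in ("blood", "hepatocyte"):
    path = os.path.join(out, f"meqtl_{tissue}.tsv")
    if os.path.exists(path):
        t = pd.read_csv(path, sep="\t")
        sig = (t["q"] < cfg["thresholds"]["meqtl_fdr"]).sum()
        print(f"{tissue}: {len(t)} cis pairs tested, {sig} at FDR < 0.05")
inst = pd.read_csv(os.path.join(out, "instruments.tsv"), sep="\t")
print("admitted instrument sets (F > 10):")
if len(inst):
    print(inst.groupby(["cpg", "tissue"]).agg(
        n_instruments=("variant_id", "size"), F=("cumulative_F", "first")
    ).round(1))
else:
    print("  none")
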