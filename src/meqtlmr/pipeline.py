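"""Stage orchestration: simulate -> ewas -> meta -> meqtl -> clump -> screen
-> gwas -> mr -> posthoc, driven by a YAML config.

Each stage reads its inputs from the output directory (written by upstream
stages or provided externally), writes tab-delimited outputs, and appends a
provenance record (stage, config hash, seed, package version, outputs) to
``run_log.json``. A stage requested without its upstream files raises an
error naming the missing dependency. One global integer seed is forked
deterministically per stage, so re-running any stage reproduces its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .assoc import ModelSpec, bh_fdr, meta_fixed, meta_to_assoc, run_ewas, run_outcome_gwas
from .datamodel import GenotypeMatrix, MethylationMatrix
from .instruments import (
    MEQTL_COVARIATES,
    clump,
    cumulative_f,
    instrument_sets_to_frame,
    instrument_sets_from_frame,
    InstrumentRecord,
    InstrumentSet,
    map_cis_meqtls,
    marginal_r2,
    qc_variants,
    screen_instruments,
)
from .mr import mr_all_cpgs, outcome_assoc_from_table
from .simulate import TruthRecord, simulate_study
from .triangulation import eqtm_map, stability, tertile_summary

log = logging.getLogger("meqtlmr")

STAGES = ["simulate", "ewas", "meta", "meqtl", "clump", "screen", "gwas", "mr", "posthoc"]

DEFAULT_THRESHOLDS = {
    "ewas_fdr": 0.05,
    "meqtl_fdr": 0.05,
    "clump_r2": 0.1,
    "screen_alpha": 0.05,
    "screen_mode": "strict",
    "min_f": 10.0,
    "mr_alpha": 0.05,
    "cis_window_bp": 2_000_000,
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", STAGES)
    cfg.setdefault("simulate", {})
    cfg.setdefault("carry_forward_probes", [])
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    cfg["thresholds"] = thresholds
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), STAGES.index(stage)])


def _log_provenance(out_dir: str, cfg: dict, stage: str, outputs: list) -> None:
    path = os.path.join(out_dir, "run_log.json")
    records = []
    if os.path.exists(path):
        with open(path) as fh:
            records = json.load(fh)
    records.append(
        {
            "stage": stage,
            "config_hash": _config_hash(cfg),
            "seed": cfg["seed"],
            "version": __version__,
            "outputs": outputs,
        }
    )
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def _require(out_dir: str, stage: str, *names: str) -> None:
    missing = [n for n in names if not os.path.exists(os.path.join(out_dir, n))]
    if missing:
        raise FileNotFoundError(
            f"stage '{stage}' requires missing upstream outputs: {missing}"
        )


def _p(out_dir: str, name: str) -> str:
    return os.path.join(out_dir, name)


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: dict, out_dir: str) -> list:
    seed = int(_stage_seed(cfg["seed"], "simulate").generate_state(1)[0] % (2**31))
    study = simulate_study(seed=seed, **cfg.get("simulate", {}))
    outputs = []

    def w(fn, obj, name):
        fn(obj, _p(out_dir, name))
        outputs.append(name)

    mio.write_annotation(study.probe_annotation, _p(out_dir, "probe_annotation.tsv"))
    outputs.append("probe_annotation.tsv")
    w(mio.write_pheno, study.cohort1_pheno, "cohort1_pheno.tsv")
    w(mio.write_matrix, study.cohort1_meth_t1, "cohort1_meth_t1.tsv")
    w(mio.write_matrix, study.cohort1_meth_t2, "cohort1_meth_t2.tsv")
    w(mio.write_pheno, study.cohort2_pheno, "cohort2_pheno.tsv")
    w(mio.write_matrix, study.cohort2_meth, "cohort2_meth.tsv")
    w(mio.write_pheno, study.meqtl_pheno, "meqtl_pheno.tsv")
    w(mio.write_matrix, study.meqtl_meth, "meqtl_meth.tsv")
    w(mio.write_matrix, study.meqtl_genotypes, "meqtl_genotypes.tsv")
    mio.write_annotation(
        study.meqtl_genotypes.annotation, _p(out_dir, "variant_annotation.tsv")
    )
    outputs.append("variant_annotation.tsv")
    w(mio.write_pheno, study.outcome_pheno, "outcome_pheno.tsv")
    w(mio.write_matrix, study.outcome_genotypes, "outcome_genotypes.tsv")
    w(mio.write_pheno, study.hep_pheno, "hep_pheno.tsv")
    w(mio.write_matrix, study.hep_meth, "hep_meth.tsv")
    w(mio.write_matrix, study.hep_genotypes, "hep_genotypes.tsv")
    for tissue, (expr, gene_ann) in study.expression.items():
        w(mio.write_matrix, expr, f"expression_{tissue}.tsv")
        mio.write_annotation(gene_ann, _p(out_dir, f"gene_annotation_{tissue}.tsv"))
        outputs.append(f"gene_annotation_{tissue}.tsv")
    study.truth.to_json(_p(out_dir, "truth.json"))
    outputs.append("truth.json")
    return outputs


def _load_meth(out_dir, name, time_point=1):
    return mio.read_matrix(
        _p(out_dir, name), "methylation",
        annotation=_p(out_dir, "probe_annotation.tsv"), time_point=time_point,
    )


def _load_geno(out_dir, name):
    return mio.read_matrix(
        _p(out_dir, name), "genotype", annotation=_p(out_dir, "variant_annotation.tsv")
    )


_EWAS_RUNS = [
    # (output, methylation, pheno, trait, transform, family, cohort, extra covars)
    ("ewas_t2d_cohort1.tsv", "cohort1_meth_t1.tsv", "cohort1_pheno.tsv",
     "t2d_status", "identity", "gaussian-on-binary", "cohort1", ("site", "bmi")),
    ("ewas_hba1c_cohort1.tsv", "cohort1_meth_t1.tsv", "cohort1_pheno.tsv",
     "hba1c", "log", "gaussian", "cohort1", ("site", "bmi")),
    ("ewas_hba1c_cohort2.tsv", "cohort2_meth.tsv", "cohort2_pheno.tsv",
     "hba1c", "log", "gaussian", "cohort2", ("bmi", "plate_position")),
    ("ewas_homa_s_cohort1.tsv", "cohort1_meth_t1.tsv", "cohort1_pheno.tsv",
     "homa_s", "log", "gaussian", "cohort1", ("site", "bmi")),
    ("ewas_homa_s_cohort2.tsv", "cohort2_meth.tsv", "cohort2_pheno.tsv",
     "homa_s", "log", "gaussian", "cohort2", ("bmi", "plate_position")),
    ("ewas_homa_b_cohort1.tsv", "cohort1_meth_t1.tsv", "cohort1_pheno.tsv",
     "homa_b", "log", "gaussian", "cohort1", ("site", "bmi")),
    ("ewas_homa_b_cohort2.tsv", "cohort2_meth.tsv", "cohort2_pheno.tsv",
     "homa_b", "log", "gaussian", "cohort2", ("bmi", "plate_position")),
]

_BASE_COVARS = ("age", "sex", "plate") + ("cd8t", "cd4t", "nk", "b", "mono", "neu")


def stage_ewas(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "ewas", "cohort1_meth_t1.tsv", "cohort1_pheno.tsv",
             "cohort2_meth.tsv", "cohort2_pheno.tsv", "probe_annotation.tsv")
    outputs = []
    lambdas = {}
    for name, meth_f, pheno_f, trait, transform, family, cohort, extra in _EWAS_RUNS:
        M = _load_meth(out_dir, meth_f)
        pheno = mio.read_pheno(_p(out_dir, pheno_f))
        covars = _BASE_COVARS + tuple(c for c in extra if c in pheno.columns)
        spec = ModelSpec(response=trait, covariates=covars, transform=transform,
                         family=family)
        table = run_ewas(M, pheno, spec, trait=trait, cohort=cohort)
        mio.write_assoc_table(table, _p(out_dir, name))
        lambdas[name] = table.attrs.get("lambda")
        outputs.append(name)
    with open(_p(out_dir, "ewas_lambdas.json"), "w") as fh:
        json.dump(lambdas, fh, indent=1)
    outputs.append("ewas_lambdas.json")
    log.info("EWAS lambdas: %s", lambdas)
    return outputs


def stage_meta(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "meta", "ewas_hba1c_cohort1.tsv", "ewas_hba1c_cohort2.tsv",
             "ewas_t2d_cohort1.tsv")
    thresholds = cfg["thresholds"]
    outputs = []
    selected: list[str] = []
    t2d = mio.read_assoc_table(_p(out_dir, "ewas_t2d_cohort1.tsv"))
    q_t2d = bh_fdr(t2d["p"].to_numpy())
    selected += list(t2d.loc[q_t2d < thresholds["ewas_fdr"], "unit_id"])
    for trait in ("hba1c", "homa_s", "homa_b"):
        tables = [
            mio.read_assoc_table(_p(out_dir, f"ewas_{trait}_cohort{k}.tsv"))
            for k in (1, 2)
            if os.path.exists(_p(out_dir, f"ewas_{trait}_cohort{k}.tsv"))
        ]
        meta = meta_fixed(tables)
        name = f"meta_{trait}.tsv"
        meta.to_csv(_p(out_dir, name), sep="\t", index=False, na_rep="NA")
        outputs.append(name)
        q = bh_fdr(meta["p_meta"].to_numpy())
        selected += list(meta.loc[q < thresholds["ewas_fdr"], "unit_id"])
        mio.write_assoc_table(
            meta_to_assoc(meta, trait), _p(out_dir, f"meta_{trait}_assoc.tsv")
        )
        outputs.append(f"meta_{trait}_assoc.tsv")
    selected += [p for p in cfg.get("carry_forward_probes", [])]
    seen, ordered = set(), []
    for pid in selected:
        if pid not in seen:
            seen.add(pid)
            ordered.append(pid)
    with open(_p(out_dir, "selected_cpgs.txt"), "w") as fh:
        fh.write("\n".join(ordered) + ("\n" if ordered else ""))
    outputs.append("selected_cpgs.txt")
    log.info("selected %d CpGs for MR", len(ordered))
    return outputs


def _read_selected(out_dir: str) -> list:
    with open(_p(out_dir, "selected_cpgs.txt")) as fh:
        return [line.strip() for line in fh if line.strip()]


def stage_meqtl(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "meqtl", "meqtl_genotypes.tsv", "meqtl_meth.tsv",
             "meqtl_pheno.tsv", "selected_cpgs.txt")
    thresholds = cfg["thresholds"]
    outputs = []
    for tissue, geno_f, meth_f, pheno_f in (
        ("blood", "meqtl_genotypes.tsv", "meqtl_meth.tsv", "meqtl_pheno.tsv"),
        ("hepatocyte", "hep_genotypes.tsv", "hep_meth.tsv", "hep_pheno.tsv"),
    ):
        if tissue == "hepatocyte" and not os.path.exists(_p(out_dir, geno_f)):
            continue
        G = _load_geno(out_dir, geno_f)
        G, qc_counts = qc_variants(G)
        M = _load_meth(out_dir, meth_f)
        pheno = mio.read_pheno(_p(out_dir, pheno_f))
        probes = [p for p in _read_selected(out_dir) if p in M.values.columns]
        table = map_cis_meqtls(
            G, M, pheno, window_bp=thresholds["cis_window_bp"],
            covariates=MEQTL_COVARIATES[tissue], probe_ids=probes,
        )
        name = f"meqtl_{tissue}.tsv"
        table.to_csv(_p(out_dir, name), sep="\t", index=False, na_rep="NA")
        outputs.append(name)
        log.info("%s meQTL scan: %d pairs, QC %s", tissue, len(table), qc_counts)
    return outputs


def stage_clump(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "clump", "meqtl_blood.tsv", "meqtl_genotypes.tsv")
    thresholds = cfg["thresholds"]
    outputs = []
    for tissue, geno_f in (("blood", "meqtl_genotypes.tsv"),
                           ("hepatocyte", "hep_genotypes.tsv")):
        meqtl_f = _p(out_dir, f"meqtl_{tissue}.tsv")
        if not os.path.exists(meqtl_f):
            continue
        table = pd.read_csv(meqtl_f, sep="\t", na_values=["NA"], keep_default_na=False)
        G = _load_geno(out_dir, geno_f)
        sig = table[table["q"] < thresholds["meqtl_fdr"]]
        rows = []
        for pid, sub in sig.groupby("probe_id", sort=True):
            for cl in clump(sub[["variant_id", "p"]], G,
                            r2_threshold=thresholds["clump_r2"]):
                rec = sub.set_index("variant_id").loc[cl.index_variant]
                rows.append(
                    {
                        "cpg": pid,
                        "tissue": tissue,
                        "variant_id": cl.index_variant,
                        "gamma": float(rec["beta"]),
                        "se_gamma": float(rec["se"]),
                        "p_gamma": float(rec["p"]),
                        "n": int(rec["n"]),
                        "n_clumped": len(cl.members),
                    }
                )
        name = f"clumped_{tissue}.tsv"
        pd.DataFrame(
            rows, columns=["cpg", "tissue", "variant_id", "gamma", "se_gamma",
                           "p_gamma", "n", "n_clumped"],
        ).to_csv(_p(out_dir, name), sep="\t", index=False, na_rep="NA")
        outputs.append(name)
    return outputs


def stage_screen(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "screen", "clumped_blood.tsv", "meqtl_genotypes.tsv",
             "meqtl_pheno.tsv")
    thresholds = cfg["thresholds"]
    outputs = []
    frames = []
    for tissue, geno_f, pheno_f in (
        ("blood", "meqtl_genotypes.tsv", "meqtl_pheno.tsv"),
        ("hepatocyte", "hep_genotypes.tsv", "hep_pheno.tsv"),
    ):
        clump_f = _p(out_dir, f"clumped_{tissue}.tsv")
        if not os.path.exists(clump_f):
            continue
        clumped = pd.read_csv(clump_f, sep="\t", na_values=["NA"], keep_default_na=False)
        if clumped.empty:
            continue
        G = _load_geno(out_dir, geno_f)
        pheno = mio.read_pheno(_p(out_dir, pheno_f))
        sets = []
        for (pid,), sub in clumped.groupby(["cpg"], sort=True):
            kept, _ = screen_instruments(
                G, pheno, list(sub["variant_id"]),
                alpha=thresholds["screen_alpha"], mode=thresholds["screen_mode"],
            )
            if not kept:
                continue
            rows = sub.set_index("variant_id").loc[kept]
            records = [
                InstrumentRecord(v, float(r["gamma"]), float(r["se_gamma"]),
                                 float(r["p_gamma"]),
                                 marginal_r2(float(r["gamma"]), float(r["se_gamma"]),
                                             int(r["n"])))
                for v, r in rows.iterrows()
            ]
            f_stat = cumulative_f([r.r2_exposure for r in records],
                                  int(rows["n"].max()))
            if f_stat > thresholds["min_f"]:
                sets.append(InstrumentSet(str(pid), tissue, records, float(f_stat)))
        frames.append(instrument_sets_to_frame(sets))
    frames = [f for f in frames if len(f)]
    inst = pd.concat(frames, ignore_index=True) if frames else instrument_sets_to_frame([])
    inst.to_csv(_p(out_dir, "instruments.tsv"), sep="\t", index=False, na_rep="NA")
    outputs.append("instruments.tsv")
    log.info("instrument sets: %d rows", len(inst))
    return outputs


def stage_gwas(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "gwas", "outcome_genotypes.tsv", "outcome_pheno.tsv",
             "instruments.tsv", "meqtl_pheno.tsv")
    inst = pd.read_csv(_p(out_dir, "instruments.tsv"), sep="\t",
                       na_values=["NA"], keep_default_na=False)
    G = _load_geno(out_dir, "outcome_genotypes.tsv")
    pheno = mio.read_pheno(_p(out_dir, "outcome_pheno.tsv"))
    exposure_ids = mio.read_pheno(_p(out_dir, "meqtl_pheno.tsv"))["sample_id"]
    variants = sorted(set(inst["variant_id"])) if len(inst) else []
    Gsub = G.subset_variants(variants) if variants else G
    table = run_outcome_gwas(Gsub, pheno, exposure_sample_ids=exposure_ids)
    mio.write_assoc_table(table, _p(out_dir, "outcome_gwas.tsv"))
    return ["outcome_gwas.tsv"]


def stage_mr(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "mr", "instruments.tsv", "outcome_gwas.tsv")
    inst = pd.read_csv(_p(out_dir, "instruments.tsv"), sep="\t",
                       na_values=["NA"], keep_default_na=False)
    outcome = outcome_assoc_from_table(
        mio.read_assoc_table(_p(out_dir, "outcome_gwas.tsv"))
    )
    sets = instrument_sets_from_frame(inst) if len(inst) else []
    results = mr_all_cpgs(sets, outcome, alpha=cfg["thresholds"]["mr_alpha"])
    results.to_csv(_p(out_dir, "mr_results.tsv"), sep="\t", index=False, na_rep="NA")
    # per-CpG scatter export (gamma vs Gamma with SEs) for plotting
    scatter = inst.merge(outcome, on="variant_id", how="inner")
    scatter.to_csv(_p(out_dir, "mr_scatter.tsv"), sep="\t", index=False, na_rep="NA")
    return ["mr_results.tsv", "mr_scatter.tsv"]


def stage_posthoc(cfg: dict, out_dir: str) -> list:
    _require(out_dir, "posthoc", "mr_results.tsv", "cohort1_meth_t1.tsv",
             "cohort1_meth_t2.tsv", "meqtl_pheno.tsv", "meqtl_meth.tsv")
    thresholds = cfg["thresholds"]
    results = pd.read_csv(_p(out_dir, "mr_results.tsv"), sep="\t",
                          na_values=["NA"], keep_default_na=False)
    causal = (
        list(results.loc[results["p"] < thresholds["mr_alpha"], "cpg"].unique())
        if len(results)
        else []
    )
    outputs = []
    M1 = _load_meth(out_dir, "cohort1_meth_t1.tsv")
    M2 = _load_meth(out_dir, "cohort1_meth_t2.tsv", time_point=2)
    rows, ba = stability(M1, M2)
    stab = pd.DataFrame([r.__dict__ for r in rows])
    stab["causal"] = stab["probe_id"].isin(causal)
    stab.to_csv(_p(out_dir, "stability.tsv"), sep="\t", index=False, na_rep="NA")
    ba.to_csv(_p(out_dir, "bland_altman.tsv"), sep="\t", index=False, na_rep="NA")
    outputs += ["stability.tsv", "bland_altman.tsv"]

    mq_pheno = mio.read_pheno(_p(out_dir, "meqtl_pheno.tsv"))
    Mq = _load_meth(out_dir, "meqtl_meth.tsv")
    from .assoc import beta_from_mvalue

    tert_rows = []
    long_ph = mq_pheno.dropna(subset=["hba1c_followup"]).set_index("sample_id")
    for pid in causal:
        if pid not in Mq.values.columns or len(long_ph) < 10:
            continue
        meth_pct = beta_from_mvalue(
            Mq.values.loc[long_ph.index, pid].to_numpy(dtype=float)
        ) * 100.0
        summ = tertile_summary(meth_pct, long_ph["hba1c_followup"].to_numpy())
        summ["probe_id"] = pid
        summ["kw_h"] = summ.attrs.get("kw_h", np.nan)
        summ["kw_p"] = summ.attrs.get("kw_p", np.nan)
        tert_rows.append(summ)
    tert = (
        pd.concat(tert_rows, ignore_index=True)
        if tert_rows
        else pd.DataFrame(columns=["tertile", "n", "median_methylation_pct",
                                   "q1", "q3", "probe_id", "kw_h", "kw_p"])
    )
    tert.to_csv(_p(out_dir, "tertiles.tsv"), sep="\t", index=False, na_rep="NA")
    outputs.append("tertiles.tsv")

    for tissue in ("blood", "adipose", "muscle"):
        expr_f = _p(out_dir, f"expression_{tissue}.tsv")
        if not os.path.exists(expr_f):
            continue
        expr = mio.read_matrix(expr_f, "expression")
        gene_ann = mio.read_annotation(_p(out_dir, f"gene_annotation_{tissue}.tsv"))
        probes = [p for p in causal if p in Mq.values.columns]
        if not probes:
            continue
        eqtm = eqtm_map(Mq, expr, gene_ann, mq_pheno, tissue, probe_ids=probes)
        name = f"eqtm_{tissue}.tsv"
        eqtm.to_csv(_p(out_dir, name), sep="\t", index=False, na_rep="NA")
        outputs.append(name)
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "ewas": stage_ewas,
    "meta": stage_meta,
    "meqtl": stage_meqtl,
    "clump": stage_clump,
    "screen": stage_screen,
    "gwas": stage_gwas,
    "mr": stage_mr,
    "posthoc": stage_posthoc,
}


def run_pipeline(config, out_dir: str | None = None) -> str:
    """Run the configured stages in canonical order; returns the output dir."""
    cfg = load_config(config)
    out_dir = out_dir or cfg.get("out_dir", "results/run")
    os.makedirs(out_dir, exist_ok=True)
    requested = cfg["stages"]
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for stage in STAGES:
        if stage not in requested:
            continue
        log.info("running stage %s", stage)
        outputs = _STAGE_FUNCS[stage](cfg, out_dir)
        _log_provenance(out_dir, cfg, stage, outputs)
    return out_dir
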