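"""Synthetic two-cohort study generator with recorded ground truth.

The generator emulates the data structure the analysis assumes: SNPs act on
CpG methylation in cis (meQTLs, effects gamma), methylation acts on a
logistic T2D liability (causal effects theta, log-odds per M-unit), and SNPs
may optionally carry direct pleiotropic effects on the liability. Around
this causal core it produces the supporting structure the pipeline needs:
two cohorts with different T2D prevalence and covariate distributions,
Houseman-style cell proportions, a second methylation time point ~7 years
later with per-CpG drift, follow-up HbA1c coupled to baseline methylation,
and gene expression correlated in cis (or placed in trans) with selected
CpGs.

Genotypes come from a latent-Gaussian LD model: two haplotype-level latent
normal draws per person with equicorrelation r within a block, thresholded
at the allele frequency, so single-variant dosages are exactly
Binomial(2, p) (Hardy-Weinberg) while within-block pairs are correlated and
across-block pairs are independent.

Every random quantity is reproducible from the seed; the generating
parameters are recorded in a :class:`TruthRecord` for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .assoc import beta_from_mvalue, mvalue_from_beta
from .datamodel import CELL_TYPES, GenotypeMatrix, MethylationMatrix

__all__ = [
    "TruthRecord",
    "LdBlock",
    "simulate_genotypes",
    "simulate_cell_proportions",
    "simulate_covariates",
    "simulate_methylation",
    "simulate_followup_methylation",
    "simulate_phenotypes",
    "simulate_expression",
    "simulate_study",
    "default_truth",
    "classify_t2d",
    "simulate_mr_dataset",
    "simulate_summary_pairs",
]

#: Mean leukocyte fractions (percent) used as the default simulation target.
DEFAULT_CELL_MEANS_PCT = (13.7, 21.3, 5.0, 8.3, 8.1, 43.2)

#: pmol/l per mU/l for insulin unit conversion.
_INSULIN_PMOL_PER_MU = 6.945


@dataclass
class LdBlock:
    """A block of variants sharing a latent-Gaussian correlation r."""

    n_variants: int
    freq_range: tuple = (0.1, 0.4)
    r: float = 0.5
    chrom: str = "20"
    start_pos: int = 1_000_000
    spacing_bp: int = 5_000


@dataclass
class TruthRecord:
    """Ground-truth generating parameters, serialisable to JSON.

    cpg_effects: probe_id -> theta (log-odds of T2D per M-unit).
    meqtl_effects: probe_id -> list of (variant_id, gamma in M-units/allele).
    pleiotropy_effects: list of (variant_id, direct log-odds per allele).
    trait_effects: probe_id -> direct effect on HbA1c (mmol/mol per M-unit).
    drift_beta: probe_id -> mean beta-scale change between time points.
    eqtm_effects: list of dicts (gene_id, probe_id, tissue, b, tss_offset).
    cohorts: name -> {"n": int, "prevalence": float}.
    ld_blocks: the genotype block structure.
    lambda_follow: coupling of baseline methylation to follow-up HbA1c.
    """

    cpg_effects: dict = field(default_factory=dict)
    meqtl_effects: dict = field(default_factory=dict)
    pleiotropy_effects: list = field(default_factory=list)
    trait_effects: dict = field(default_factory=dict)
    drift_beta: dict = field(default_factory=dict)
    eqtm_effects: list = field(default_factory=list)
    cohorts: dict = field(default_factory=dict)
    ld_blocks: list = field(default_factory=list)
    lambda_follow: float = 2.0

    def to_json(self, path: str) -> None:
        d = asdict(self)
        d["ld_blocks"] = [asdict(b) if isinstance(b, LdBlock) else b for b in self.ld_blocks]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        d["ld_blocks"] = [LdBlock(**{**b, "freq_range": tuple(b["freq_range"])})
                          for b in d.get("ld_blocks", [])]
        d["meqtl_effects"] = {
            k: [tuple(x) for x in v] for k, v in d.get("meqtl_effects", {}).items()
        }
        d["pleiotropy_effects"] = [tuple(x) for x in d.get("pleiotropy_effects", [])]
        return cls(**d)

    def variant_ids(self) -> set:
        ids = {v for eff in self.meqtl_effects.values() for v, _ in eff}
        ids |= {v for v, _ in self.pleiotropy_effects}
        return ids


def simulate_genotypes(
    n: int, blocks, seed=None, rng: np.random.Generator | None = None,
    prefix: str = "rs", miss_rate: float = 0.0,
) -> GenotypeMatrix:
    """Draw dosages for ``n`` samples from latent-Gaussian LD blocks.

    Within a block, alleles share a common latent factor with weight
    sqrt(r); across blocks variants are independent. Marginal dosages are
    Binomial(2, freq), i.e. Hardy-Weinberg genotype classes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cols, ann_rows = [], []
    counter = 0
    for bi, block in enumerate(blocks):
        if not 0.0 <= block.r < 1.0:
            raise ValueError(f"block {bi}: within-block r must be in [0, 1)")
        m = block.n_variants
        lo, hi = block.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"block {bi}: allele frequencies must be in (0, 1)")
        freqs = rng.uniform(lo, hi, size=m)
        sr, sc = np.sqrt(block.r), np.sqrt(1.0 - block.r)
        dos = np.zeros((n, m))
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            latent = sr * shared + sc * rng.standard_normal((n, m))
            dos += (latent < stats.norm.ppf(freqs)[None, :]).astype(float)
        if miss_rate > 0:
            mask = rng.random((n, m)) < miss_rate
            dos[mask] = np.nan
        for j in range(m):
            vid = f"{prefix}{counter}"
            counter += 1
            ann_rows.append(
                {
                    "variant_id": vid,
                    "chrom": block.chrom,
                    "pos": block.start_pos + j * block.spacing_bp,
                    "ref_allele": "A",
                    "alt_allele": "G",
                    "alt_freq": float(freqs[j]),
                    "info_score": 1.0,
                    "call_rate": 1.0 - miss_rate,
                    "hwe_p": 1.0,
                    "block": bi,
                }
            )
        cols.append(dos)
    ann = pd.DataFrame(ann_rows).set_index("variant_id")
    sample_ids = [f"s{i}" for i in range(n)]
    dosages = pd.DataFrame(np.hstack(cols), index=sample_ids, columns=ann.index)
    return GenotypeMatrix(dosages, ann)


def simulate_cell_proportions(
    n: int, seed=None, rng=None, means_pct=DEFAULT_CELL_MEANS_PCT,
    concentration: float = 17.0,
) -> pd.DataFrame:
    """Dirichlet leukocyte fractions with configurable mean targets.

    ``concentration`` is the Dirichlet total alpha; ~17 reproduces the
    between-person spread typical of Houseman estimates (SD ~0.12 for the
    neutrophil fraction).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    mean = np.asarray(means_pct, dtype=float)
    mean = mean / mean.sum()
    draws = rng.dirichlet(mean * concentration, size=n)
    return pd.DataFrame(draws, columns=CELL_TYPES)


def simulate_covariates(
    n: int,
    rng: np.random.Generator,
    cohort: str = "cohort1",
    sites=("rural", "urban", "amsterdam"),
    age_mean: float = 46.7,
    age_sd: float = 11.0,
    frac_female: float = 0.63,
    bmi_mean: float = 26.0,
    bmi_sd: float = 5.2,
    smoker_rate: float = 0.025,
    n_plates: int = 8,
    cell_means_pct=DEFAULT_CELL_MEANS_PCT,
    sample_prefix: str = "s",
) -> pd.DataFrame:
    """Demographics, anthropometry, technical and cell-count covariates."""
    pheno = pd.DataFrame({"sample_id": [f"{sample_prefix}{i}" for i in range(n)]})
    pheno["age"] = np.clip(rng.normal(age_mean, age_sd, n), 18, 95)
    pheno["sex"] = np.where(rng.random(n) < frac_female, "female", "male")
    pheno["site"] = rng.choice(list(sites), size=n)
    pheno["bmi"] = np.clip(rng.normal(bmi_mean, bmi_sd, n), 15, 60)
    pheno["waist"] = 55 + 1.5 * pheno["bmi"] + rng.normal(0, 5, n)
    pheno["hip"] = 60 + 1.5 * pheno["bmi"] + rng.normal(0, 5, n)
    pheno["smoker"] = rng.random(n) < smoker_rate
    pheno["plate"] = [f"p{j}" for j in rng.integers(0, n_plates, n)]
    cells = simulate_cell_proportions(n, rng=rng, means_pct=cell_means_pct)
    pheno = pd.concat([pheno, cells], axis=1)
    pheno["cohort"] = cohort
    return pheno


def simulate_methylation(
    G: GenotypeMatrix,
    probe_annotation: pd.DataFrame,
    truth: TruthRecord,
    pheno: pd.DataFrame,
    noise_sd: float = 0.8,
    seed=None,
    rng=None,
    intercepts: dict | None = None,
    covariate_effects: bool = True,
) -> MethylationMatrix:
    """M-value methylation: intercept + sum(gamma * dosage) + covariates + noise.

    Probes listed in ``truth.meqtl_effects`` receive their cis SNP effects;
    every probe receives small age/sex/cell-composition/plate effects when
    ``covariate_effects`` is on, plus N(0, noise_sd^2) residual noise.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    missing = truth.variant_ids() - set(G.dosages.columns)
    if missing & {v for eff in truth.meqtl_effects.values() for v, _ in eff}:
        raise ValueError(f"truth meQTL variants absent from genotypes: {sorted(missing)[:5]}")
    samples = list(G.dosages.index)
    n = len(samples)
    probes = list(probe_annotation.index)
    intercepts = intercepts or {}
    ph = pheno.set_index("sample_id").loc[samples]
    age_c = (ph["age"].to_numpy(dtype=float) - 50.0) / 10.0
    sex_f = (ph["sex"] == "female").to_numpy(dtype=float)
    cd8 = ph["cd8t"].to_numpy(dtype=float) if "cd8t" in ph.columns else np.zeros(n)
    plate_codes = (
        ph["plate"].astype("category").cat.codes.to_numpy(dtype=float)
        if "plate" in ph.columns
        else np.zeros(n)
    )
    M = np.empty((n, len(probes)))
    for j, pid in enumerate(probes):
        mu = np.full(n, intercepts.get(pid, rng.uniform(-3.5, 3.5)))
        for vid, gamma in truth.meqtl_effects.get(pid, []):
            mu += gamma * np.nan_to_num(G.dosages[vid].to_numpy(dtype=float))
        if covariate_effects:
            mu += (
                rng.normal(0, 0.03) * age_c
                + rng.normal(0, 0.05) * sex_f
                + rng.normal(0, 0.3) * (cd8 - np.mean(cd8))
                + rng.normal(0, 0.02) * plate_codes
            )
        M[:, j] = mu + rng.normal(0, noise_sd, n)
    values = pd.DataFrame(M, index=samples, columns=probes)
    return MethylationMatrix(values, probe_annotation, scale="m_value", time_point=1)


def simulate_followup_methylation(
    M1: MethylationMatrix,
    truth: TruthRecord,
    drift_sd_beta: float = 0.01,
    seed=None,
    rng=None,
) -> MethylationMatrix:
    """Second methylation time point: beta-scale drift per CpG plus noise.

    Each probe's beta-values shift by N(drift_j, drift_sd^2) where drift_j
    comes from ``truth.drift_beta`` (default 0), then convert back to the M
    scale. Emulates a repeat array ~6-7 years after baseline.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    B = beta_from_mvalue(M1.values.to_numpy(dtype=float))
    drift = np.array([truth.drift_beta.get(p, 0.0) for p in M1.values.columns])
    B2 = B + drift[None, :] + rng.normal(0, drift_sd_beta, B.shape)
    B2 = np.clip(B2, 1e-6, 1 - 1e-6)
    values = pd.DataFrame(
        mvalue_from_beta(B2), index=M1.values.index, columns=M1.values.columns
    )
    return MethylationMatrix(values, M1.annotation, scale="m_value", time_point=2)


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Liability intercept alpha with mean expit(alpha + eta) = prevalence."""
    return brentq(lambda a: np.mean(expit(a + eta)) - prevalence, -30.0, 30.0)


def classify_t2d(fasting_glucose, med_use=None) -> np.ndarray:
    """T2D case definition: fasting glucose >= 7.0 mmol/l or medication use."""
    g = np.asarray(fasting_glucose, dtype=float)
    cases = g >= 7.0
    if med_use is not None:
        cases = cases | np.asarray(med_use, dtype=bool)
    return cases


def _trunc_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def simulate_phenotypes(
    G: GenotypeMatrix | None,
    M: MethylationMatrix,
    truth: TruthRecord,
    pheno: pd.DataFrame,
    prevalence: float = 0.05,
    seed=None,
    rng=None,
    med_use_rate_cases: float = 0.0,
    covariate_liability: bool = True,
    followup_fraction: float = 0.0,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Complete the phenotype table from the causal model.

    Liability: L = alpha + sum_j theta_j (M_ij - mean_j) + pleiotropic dosage
    terms + (optionally) age/BMI terms; alpha is solved so the mean of
    expit(L) hits the target prevalence; T2D ~ Bernoulli(expit(L)).
    Fasting glucose is drawn conditional on case status (truncated normals
    on either side of the 7.0 mmol/l diagnostic cut, with an affine-in-
    liability mean), so :func:`classify_t2d` reproduces the drawn label.
    HbA1c tracks glucose plus direct CpG trait effects; insulin is
    log-normal and increases with liability; HOMA indices use the classic
    formulas (HOMA-IR = glucose x insulin[mU/l] / 22.5, HOMA-S = 100/IR,
    HOMA-B = 20 x insulin / (glucose - 3.5)); glucose draws <= 3.5 for the
    HOMA-B denominator are re-drawn a bounded number of times.
    Follow-up HbA1c (for a random subset) couples to baseline methylation
    through ``truth.lambda_follow``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = pheno.copy()
    samples = list(out["sample_id"])
    Mv = M.values.loc[samples]
    eta = np.zeros(len(samples))
    cpg_signal = np.zeros(len(samples))
    for pid, theta in truth.cpg_effects.items():
        if pid in Mv.columns:
            col = Mv[pid].to_numpy(dtype=float)
            cpg_signal += theta * (col - col.mean())
    eta += cpg_signal
    if G is not None:
        for vid, delta in truth.pleiotropy_effects:
            if vid in G.dosages.columns:
                d = G.dosages[vid].reindex(samples).to_numpy(dtype=float)
                eta += delta * (np.nan_to_num(d) - np.nanmean(d))
    if covariate_liability:
        age_c = (out["age"].to_numpy(dtype=float) - 50.0) / 10.0
        bmi_c = (out["bmi"].to_numpy(dtype=float) - 27.0) / 5.0
        eta += 0.30 * age_c + 0.35 * bmi_c
    alpha = _solve_intercept(eta, prevalence)
    t2d = rng.random(len(samples)) < expit(alpha + eta)

    glucose = np.empty(len(samples))
    ctrl, case = ~t2d, t2d
    for _ in range(max_retries):
        glucose[ctrl] = _trunc_normal(
            rng, 5.2 + 0.25 * eta[ctrl], 0.7, 3.6, 6.999, ctrl.sum()
        )
        glucose[case] = _trunc_normal(
            rng, 8.5 + 0.4 * eta[case], 1.6, 7.0, 20.0, case.sum()
        )
        if np.all(glucose > 3.5):
            break
    else:
        raise RuntimeError("could not draw glucose > 3.5 mmol/l for HOMA-B")

    trait_signal = np.zeros(len(samples))
    for pid, phi in truth.trait_effects.items():
        if pid in Mv.columns:
            col = Mv[pid].to_numpy(dtype=float)
            trait_signal += phi * (col - col.mean())
    hba1c = 35.0 + 5.5 * (glucose - 5.3) + trait_signal + rng.normal(0, 3.0, len(samples))
    hba1c = np.clip(hba1c, 15.0, 140.0)

    ln_insulin = np.log(30.0) + 0.25 * eta + rng.normal(0, 0.55, len(samples))
    insulin_pmol = np.exp(ln_insulin)
    insulin_mu = insulin_pmol / _INSULIN_PMOL_PER_MU
    homa_ir = glucose * insulin_mu / 22.5
    out["fasting_glucose"] = glucose
    out["insulin"] = insulin_pmol
    out["hba1c"] = hba1c
    out["homa_s"] = 100.0 / homa_ir
    out["homa_b"] = 20.0 * insulin_mu / (glucose - 3.5)
    out["t2d_med_use"] = t2d & (rng.random(len(samples)) < med_use_rate_cases)
    out["t2d_status"] = classify_t2d(glucose, out["t2d_med_use"])
    out["hba1c_followup"] = np.nan
    if followup_fraction > 0:
        k = int(round(followup_fraction * len(samples)))
        idx = rng.choice(len(samples), size=k, replace=False)
        fup = (
            hba1c[idx]
            + truth.lambda_follow * cpg_signal[idx]
            + rng.normal(0, 2.0, k)
        )
        col = out["hba1c_followup"].to_numpy()
        col[idx] = fup
        out["hba1c_followup"] = col
    return out


def simulate_expression(
    M: MethylationMatrix,
    eqtm_effects,
    tissue: str,
    n: int,
    seed=None,
    rng=None,
    pheno: pd.DataFrame | None = None,
    n_background_genes: int = 20,
    noise_sd: float = 1.0,
):
    """Expression matrix with configured CpG -> gene couplings for one tissue.

    Each configured eQTM gene g gets expr = a_g + b_g * M[:, cpg(g)] + small
    age/sex terms + noise, with its TSS placed ``tss_offset`` bp from the
    CpG (cis within 1 Mb, trans beyond). Background genes are noise with
    random distant TSS. Returns ``(expression frame, gene annotation)`` for
    ``n`` samples drawn from the methylation matrix.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    samples = list(M.values.index[:n])
    genes, ann_rows = {}, []
    ph = (
        pheno.set_index("sample_id").loc[samples]
        if pheno is not None and "sample_id" in pheno.columns
        else None
    )
    age_c = (
        (ph["age"].to_numpy(dtype=float) - 50.0) / 10.0
        if ph is not None
        else np.zeros(len(samples))
    )
    for eff in eqtm_effects:
        if eff.get("tissue") not in (None, tissue):
            continue
        pid = eff["probe_id"]
        prow = M.annotation.loc[pid]
        m = M.values.loc[samples, pid].to_numpy(dtype=float)
        expr = (
            eff.get("a", 5.0)
            + eff["b"] * m
            + 0.05 * age_c
            + rng.normal(0, eff.get("noise_sd", noise_sd), len(samples))
        )
        genes[eff["gene_id"]] = expr
        ann_rows.append(
            {
                "gene_id": eff["gene_id"],
                "chrom": str(prow["chrom"]),
                "tss": int(prow["pos"]) + int(eff.get("tss_offset", 100_000)),
                "strand": eff.get("strand", "+"),
            }
        )
    first_chrom = str(M.annotation["chrom"].iloc[0])
    for k in range(n_background_genes):
        gid = f"GENE_BG{k}"
        genes[gid] = 5.0 + rng.normal(0, noise_sd, len(samples))
        ann_rows.append(
            {
                "gene_id": gid,
                "chrom": first_chrom,
                "tss": int(rng.integers(1, 60_000_000)),
                "strand": "+",
            }
        )
    expr = pd.DataFrame(genes, index=samples)
    gene_ann = pd.DataFrame(ann_rows).set_index("gene_id")
    return expr, gene_ann


# --------------------------------------------------------------------------
# Default study configuration: the reference conditions at desk scale.

_OR_BLOOD = 0.76   # protective causal CpG, blood instruments
_OR_HEP = 1.29     # risk causal CpG, hepatocyte instrument


def default_truth(
    n_background_probes: int = 60,
    n_background_blocks: int = 6,
    rng: np.random.Generator | None = None,
) -> tuple[TruthRecord, pd.DataFrame]:
    """Default ground truth and probe annotation for the shipped study.

    Two causal CpGs: ``cg_blood_causal`` (theta = ln 0.76, three independent
    cis meQTLs in separate LD blocks, mean methylation ~92%) and
    ``cg_hep_causal`` (theta = ln 1.29, one strong hepatocyte meQTL, mean
    ~74%, with a direct negative HbA1c association in blood). Temporal drift
    -0.42 and -0.95 percentage points over the follow-up interval, and three
    configured eQTM couplings (two cis in muscle at -0.366 and -1.258, one
    trans in blood at -0.045, 1.94 Mb away).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    chrom = "20"
    blocks = [
        LdBlock(8, (0.25, 0.35), 0.6, chrom, 30_000_000, 4_000),
        LdBlock(8, (0.25, 0.35), 0.6, chrom, 30_300_000, 4_000),
        LdBlock(8, (0.25, 0.35), 0.6, chrom, 30_600_000, 4_000),
        LdBlock(6, (0.20, 0.40), 0.6, chrom, 45_000_000, 4_000),
    ]
    pos = 5_000_000
    for _ in range(n_background_blocks):
        blocks.append(LdBlock(6, (0.05, 0.45), 0.5, chrom, pos, 5_000))
        pos += 1_500_000
    truth = TruthRecord(
        cpg_effects={
            "cg_blood_causal": float(np.log(_OR_BLOOD)),
            "cg_hep_causal": float(np.log(_OR_HEP)),
        },
        meqtl_effects={
            # one causal variant per LD block -> three independent instruments
            "cg_blood_causal": [("rs0", 0.45), ("rs8", 0.35), ("rs16", 0.40)],
            # a single strong hepatocyte meQTL: detectable at the small (n=56)
            # hepatocyte panel, ~40% of M-value variance explained
            "cg_hep_causal": [("rs24", 1.0)],
        },
        pleiotropy_effects=[],
        trait_effects={"cg_hep_causal": -3.0},
        drift_beta={"cg_blood_causal": -0.0042, "cg_hep_causal": -0.0095},
        eqtm_effects=[
            # noise levels chosen so the three couplings land in their
            # respective evidence tiers (strict FDR, exploratory FDR, strict)
            {"gene_id": "GENE_MUSCLE_CIS", "probe_id": "cg_blood_causal",
             "tissue": "muscle", "b": -0.366, "tss_offset": 300_000, "a": 6.0,
             "noise_sd": 0.4},
            {"gene_id": "GENE_MUSCLE_CIS2", "probe_id": "cg_blood_causal",
             "tissue": "muscle", "b": -1.258, "tss_offset": 450_000, "a": 8.0,
             "noise_sd": 4.0},
            {"gene_id": "GENE_BLOOD_TRANS", "probe_id": "cg_blood_causal",
             "tissue": "blood", "b": -0.045, "tss_offset": 1_940_000, "a": 4.0,
             "noise_sd": 0.05},
        ],
        cohorts={
            "cohort1": {"n": 879, "prevalence": 0.047},
            "cohort2_ewas": {"n": 332, "prevalence": 0.018},
            "cohort2_meqtl": {"n": 606, "prevalence": 0.462},
            "cohort2_outcome": {"n": 4000, "prevalence": 0.487},
        },
        ld_blocks=blocks,
        lambda_follow=2.0,
    )
    # probe annotation: causal probes sit inside their meQTL blocks' windows
    rows = [
        {"probe_id": "cg_blood_causal", "chrom": chrom, "pos": 30_310_000,
         "gene_label": "GENE_AT_TSS"},
        {"probe_id": "cg_hep_causal", "chrom": chrom, "pos": 45_010_000,
         "gene_label": None},
    ]
    for k in range(n_background_probes):
        rows.append(
            {
                "probe_id": f"cg_bg{k}",
                "chrom": chrom,
                "pos": int(rng.integers(1_000_000, 60_000_000)),
                "gene_label": None,
            }
        )
    probe_ann = pd.DataFrame(rows).set_index("probe_id")
    return truth, probe_ann


_M_INTERCEPTS = {
    # ~92% and ~74% methylated at baseline, matching the causal CpGs' levels
    "cg_blood_causal": 2.6,
    "cg_hep_causal": 1.0,
}


@dataclass
class SyntheticStudy:
    """Everything one study run produces, plus its ground truth."""

    truth: TruthRecord
    probe_annotation: pd.DataFrame
    cohort1_pheno: pd.DataFrame
    cohort1_meth_t1: MethylationMatrix
    cohort1_meth_t2: MethylationMatrix
    cohort2_pheno: pd.DataFrame
    cohort2_meth: MethylationMatrix
    meqtl_pheno: pd.DataFrame
    meqtl_meth: MethylationMatrix
    meqtl_genotypes: GenotypeMatrix
    outcome_pheno: pd.DataFrame
    outcome_genotypes: GenotypeMatrix
    expression: dict
    hep_pheno: pd.DataFrame | None = None
    hep_meth: MethylationMatrix | None = None
    hep_genotypes: GenotypeMatrix | None = None


def simulate_study(
    seed: int = 0,
    n_cohort1: int = 879,
    n_cohort2_ewas: int = 332,
    n_meqtl: int = 606,
    n_outcome: int = 4000,
    n_hep: int = 56,
    n_background_probes: int = 60,
    noise_sd: float = 0.8,
    truth: TruthRecord | None = None,
    probe_annotation: pd.DataFrame | None = None,
    followup_fraction_meqtl: float = 0.23,  # ~138 of 606
) -> SyntheticStudy:
    """Generate the full two-cohort study under the default ground truth.

    Cohort 1 (population-based, three recruitment sites, T2D prevalence
    4.7%, no medicated participants) provides the T2D EWAS and the two
    methylation time points. Cohort 2 provides the glycaemic-trait EWAS
    subset (single site), the T2D-enriched meQTL subset (prevalence 46.2%,
    genotypes + methylation + longitudinal HbA1c subset), the disjoint
    outcome-GWAS sample (prevalence 48.7%), and tissue expression subsets.
    A small hepatocyte panel (n=56) supplies the hepatocyte meQTL tissue.
    """
    ss = np.random.SeedSequence(seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ["truth", "c1", "c2", "meqtl", "outcome", "hep", "expr"], ss.spawn(7)
    )}
    if truth is None or probe_annotation is None:
        truth, probe_annotation = default_truth(
            n_background_probes=n_background_probes, rng=rngs["truth"]
        )

    def _cohort(rng, n, prefix, prevalence, med_rate, with_geno, followup=0.0,
                sites=("rural", "urban", "amsterdam"), age_mean=46.7, bmi_mean=26.0,
                frac_female=0.63, covars_extra=None):
        pheno = simulate_covariates(
            n, rng, sites=sites, age_mean=age_mean, bmi_mean=bmi_mean,
            frac_female=frac_female, sample_prefix=prefix,
        )
        G = simulate_genotypes(n, truth.ld_blocks, rng=rng)
        G = GenotypeMatrix(G.dosages.set_axis(pheno["sample_id"]), G.annotation)
        M = simulate_methylation(
            G, probe_annotation, truth, pheno, noise_sd=noise_sd, rng=rng,
            intercepts=_M_INTERCEPTS,
        )
        pheno = simulate_phenotypes(
            G, M, truth, pheno, prevalence=prevalence, rng=rng,
            med_use_rate_cases=med_rate, followup_fraction=followup,
        )
        if covars_extra:
            for k, v in covars_extra(rng, n).items():
                pheno[k] = v
        return pheno, M, (G if with_geno else None)

    c1_pheno, c1_m1, _ = _cohort(
        rngs["c1"], n_cohort1, "r", truth.cohorts["cohort1"]["prevalence"], 0.0, False
    )
    c1_m2 = simulate_followup_methylation(c1_m1, truth, rng=rngs["c1"])

    c2_pheno, c2_m, _ = _cohort(
        rngs["c2"], n_cohort2_ewas, "a", truth.cohorts["cohort2_ewas"]["prevalence"],
        0.0, False, sites=("ibadan",), age_mean=55.4, bmi_mean=30.8, frac_female=0.765,
    )
    c2_pheno["plate_position"] = [
        f"pos{j}" for j in rngs["c2"].integers(0, 12, n_cohort2_ewas)
    ]

    mq_pheno, mq_m, mq_g = _cohort(
        rngs["meqtl"], n_meqtl, "q", truth.cohorts["cohort2_meqtl"]["prevalence"],
        0.98, True, followup=followup_fraction_meqtl,
        sites=("ibadan",), age_mean=57.5, bmi_mean=31.2, frac_female=0.779,
    )

    def _pcs(rng, n):
        return {f"pc{k}": rng.normal(0, 1, n) for k in (1, 2, 3)}

    out_pheno, _, out_g = _cohort(
        rngs["outcome"], n_outcome, "o", truth.cohorts["cohort2_outcome"]["prevalence"],
        0.96, True, sites=("ibadan", "accra"), age_mean=49.6, bmi_mean=26.4,
        frac_female=0.60, covars_extra=_pcs,
    )

    hep_pheno, hep_m, hep_g = _cohort(
        rngs["hep"], n_hep, "h", 0.3, 0.0, True,
        sites=("usa",), age_mean=39.2, bmi_mean=28.0, frac_female=0.446,
    )
    hep_pheno["ancestry_fraction"] = np.clip(
        rngs["hep"].normal(0.83, 0.1, n_hep), 0.3, 1.0
    )

    expression = {}
    for tissue, n_t in (("blood", 77), ("adipose", 49), ("muscle", 55)):
        expr, gene_ann = simulate_expression(
            mq_m, truth.eqtm_effects, tissue, min(n_t, n_meqtl),
            rng=rngs["expr"], pheno=mq_pheno,
        )
        expression[tissue] = (expr, gene_ann)

    return SyntheticStudy(
        truth=truth,
        probe_annotation=probe_annotation,
        cohort1_pheno=c1_pheno,
        cohort1_meth_t1=c1_m1,
        cohort1_meth_t2=c1_m2,
        cohort2_pheno=c2_pheno,
        cohort2_meth=c2_m,
        meqtl_pheno=mq_pheno,
        meqtl_meth=mq_m,
        meqtl_genotypes=mq_g,
        outcome_pheno=out_pheno,
        outcome_genotypes=out_g,
        expression=expression,
        hep_pheno=hep_pheno,
        hep_meth=hep_m,
        hep_genotypes=hep_g,
    )


# --------------------------------------------------------------------------
# Lean MR replicate generators for simulation studies (calibration, power).


def simulate_mr_dataset(
    theta: float,
    gammas=(0.45, 0.35, 0.40),
    freqs=(0.3, 0.3, 0.3),
    n_exposure: int = 600,
    n_outcome: int = 4000,
    noise_sd: float = 0.8,
    prevalence: float = 0.45,
    pleiotropy: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One two-sample MR replicate at the individual level.

    Exposure sample: independent SNPs, M = sum(gamma G) + N(0, noise_sd^2);
    per-SNP marginal OLS gives (gamma_hat, se). Outcome sample: fresh
    genotypes, the same methylation model, logistic liability
    alpha + theta (M - mean) + pleiotropy * sum(G - mean); per-SNP logistic
    fits give (Gamma_hat, se). Returns harmonised pairs ready for the MR
    estimators.
    """
    rng = rng if rng is not None else np.random.default_rng()
    gammas = np.asarray(gammas, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    J = gammas.size

    Ge = rng.binomial(2, freqs, size=(n_exposure, J)).astype(float)
    Me = Ge @ gammas + rng.normal(0, noise_sd, n_exposure)
    gh = np.empty(J)
    gse = np.empty(J)
    for j in range(J):
        x = Ge[:, j]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        b = float(xc @ (Me - Me.mean())) / sxx
        resid = (Me - Me.mean()) - b * xc
        s2 = float(resid @ resid) / (n_exposure - 2)
        gh[j], gse[j] = b, np.sqrt(s2 / sxx)

    Go = rng.binomial(2, freqs, size=(n_outcome, J)).astype(float)
    Mo = Go @ gammas + rng.normal(0, noise_sd, n_outcome)
    eta = theta * (Mo - Mo.mean()) + pleiotropy * (Go - Go.mean(axis=0)).sum(axis=1)
    alpha = _solve_intercept(eta, prevalence)
    y = (rng.random(n_outcome) < expit(alpha + eta)).astype(float)
    Gh = np.empty(J)
    Gse = np.empty(J)
    for j in range(J):
        b, se = _fast_logit_slope(Go[:, j], y)
        Gh[j], Gse[j] = b, se
    pairs = pd.DataFrame(
        {
            "variant_id": [f"iv{j}" for j in range(J)],
            "gamma": gh,
            "se_gamma": gse,
            "Gamma": Gh,
            "se_Gamma": Gse,
        }
    )
    flip = pairs["gamma"] < 0
    pairs.loc[flip, ["gamma", "Gamma"]] *= -1.0
    return pairs


def _fast_logit_slope(x: np.ndarray, y: np.ndarray, max_iter: int = 25):
    """Newton-Raphson ML logistic fit of y on [1, x]; returns slope and SE."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(X @ beta)
    W = p * (1 - p)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    return float(beta[1]), float(np.sqrt(cov[1, 1]))


def simulate_summary_pairs(
    theta: float,
    gammas,
    se_gamma: float = 0.04,
    se_Gamma: float = 0.05,
    pleiotropy_intercept: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Summary-statistic-level MR replicate.

    gamma_hat_j ~ N(gamma_j, se_gamma^2);
    Gamma_hat_j ~ N(theta gamma_j + alpha_0, se_Gamma^2) where alpha_0 is a
    shared directional pleiotropy intercept (independent of gamma, i.e. the
    InSIDE condition holds). Used by the Rucker branch-behaviour and Egger
    calibration studies.
    """
    rng = rng if rng is not None else np.random.default_rng()
    g = np.asarray(gammas, dtype=float)
    gh = g + rng.normal(0, se_gamma, g.size)
    Gh = theta * g + pleiotropy_intercept + rng.normal(0, se_Gamma, g.size)
    pairs = pd.DataFrame(
        {
            "variant_id": [f"iv{j}" for j in range(g.size)],
            "gamma": gh,
            "se_gamma": se_gamma,
            "Gamma": Gh,
            "se_Gamma": se_Gamma,
        }
    )
    flip = pairs["gamma"] < 0
    pairs.loc[flip, ["gamma", "Gamma"]] *= -1.0
    return pairs
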