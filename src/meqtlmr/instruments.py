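"""MR instrument construction from cis-meQTLs.

Steps, in pipeline order: per-marker genotype QC (missingness, MAF, exact
Hardy-Weinberg test, imputation INFO score), additive cis-meQTL mapping
within a window around each CpG (variants overlapping the probe excluded),
greedy LD clumping at r^2 < 0.1 with the lowest-p variant as each clump's
index, cumulative F statistics for instrument strength, and a
confounder-association screen of the selected instruments.

The meQTL model is fixed-effects OLS of methylation M-values on dosage with
the stage covariates; relatedness (mixed-model) adjustment is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import ModelSpec, bh_fdr, scan_units, _logit, _ols
from .datamodel import GenotypeMatrix, in_window

__all__ = [
    "hwe_exact",
    "qc_variants",
    "map_cis_meqtls",
    "ld_r2",
    "Clump",
    "clump",
    "cumulative_f",
    "screen_instruments",
    "InstrumentRecord",
    "InstrumentSet",
    "build_instrument_sets",
    "instrument_sets_to_frame",
    "instrument_sets_from_frame",
]

#: Default covariates per meQTL tissue.
MEQTL_COVARIATES = {
    "blood": ("age", "sex", "t2d_med_use", "cd8t", "cd4t", "nk", "b", "mono", "neu"),
    "hepatocyte": ("age", "sex", "ancestry_fraction"),
}


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one (the standard
    exact formulation; more robust than the chi-square at small counts).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor-allele copies
    # distribution of het counts given n and rare-allele count
    het_min = rare % 2
    probs = {}
    # start from mid heterozygote count and recurse outwards for stability
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid - het_min) % 2 != 0:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((r-h+2)/2 * (c-h+2)/2) ...
    def hom_rare(h):
        return (rare - h) // 2

    def hom_common(h):
        return n - h - hom_rare(h)

    h = mid
    while h >= het_min + 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            4.0 * (hom_rare(h) + 1) * (hom_common(h) + 1)
        )
        h -= 2
    h = mid
    while h <= rare - 2 and hom_rare(h) > 0:
        probs[h + 2] = probs[h] * 4.0 * hom_rare(h) * hom_common(h) / (
            (h + 2.0) * (h + 1.0)
        )
        h += 2
    total = sum(probs.values())
    obs = probs.get(n_het)
    if obs is None:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return float(min(p, 1.0))


def qc_variants(
    G: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-6,
    min_info: float = 0.8,
):
    """Per-marker QC: drop variants failing any filter; report counts.

    Filters: call-rate missingness > ``max_missing``; minor allele frequency
    < ``min_maf``; exact Hardy-Weinberg p <= ``hwe_alpha`` (computed from
    rounded dosages); imputation INFO score < ``min_info`` (taken from the
    annotation). Returns ``(filtered GenotypeMatrix, counts dict)``.
    """
    D = G.dosages.to_numpy(dtype=float)
    n = D.shape[0]
    miss = np.mean(np.isnan(D), axis=0)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    hwe_p = np.ones(D.shape[1])
    for j in range(D.shape[1]):
        col = D[~np.isnan(D[:, j]), j]
        g = np.rint(col).astype(int)
        hwe_p[j] = hwe_exact(int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)))
    info = (
        G.annotation["info_score"].reindex(G.dosages.columns).to_numpy(dtype=float)
        if "info_score" in G.annotation.columns
        else np.ones(D.shape[1])
    )
    fail_miss = miss > max_missing
    fail_maf = maf < min_maf
    fail_hwe = hwe_p <= hwe_alpha
    fail_info = np.nan_to_num(info, nan=1.0) < min_info
    fail_any = fail_miss | fail_maf | fail_hwe | fail_info
    counts = {
        "n_input": int(D.shape[1]),
        "missingness": int(fail_miss.sum()),
        "maf": int(fail_maf.sum()),
        "hwe": int(fail_hwe.sum()),
        "info": int(fail_info.sum()),
        "removed": int(fail_any.sum()),
        "kept": int((~fail_any).sum()),
    }
    keep = list(G.dosages.columns[~fail_any])
    return GenotypeMatrix(G.dosages[keep], G.annotation.loc[keep]), counts


def ld_r2(G: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation of two dosage columns over complete cases."""
    x = G.dosages[v1].to_numpy(dtype=float)
    y = G.dosages[v2].to_numpy(dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def map_cis_meqtls(
    G: GenotypeMatrix,
    M,
    pheno: pd.DataFrame,
    window_bp: int = 2_000_000,
    covariates=MEQTL_COVARIATES["blood"],
    probe_ids=None,
    probe_overlap_bp: int = 0,
) -> pd.DataFrame:
    """Additive cis-meQTL scan: M-value ~ dosage + covariates per pair.

    Tests every (CpG, variant) pair on the same chromosome with
    ``|pos_variant - pos_cpg| <= window_bp // 2`` ("a 2 Mb region around the
    CpG" = +/-1 Mb). Variants overlapping the probe coordinate (within
    ``probe_overlap_bp``) are excluded before testing. BH-FDR is computed
    over all tested pairs. Returns a frame with variant_id, probe_id, beta
    (gamma), se, p, q, n, distance.
    """
    covariates = tuple(c for c in covariates if c in pheno.columns)
    ph = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    common = [s for s in M.values.index if s in ph.index]
    if not common:
        raise ValueError("no overlapping samples between methylation and phenotypes")
    ph = ph.loc[common]
    vann = G.annotation
    results = []
    probe_list = probe_ids if probe_ids is not None else M.probe_ids
    for pid in probe_list:
        prow = M.annotation.loc[pid]
        same_chrom = vann.index[vann["chrom"].astype(str) == str(prow["chrom"])]
        cand = [
            v
            for v in same_chrom
            if in_window(vann.at[v, "pos"], prow["pos"], window_bp)
            and abs(int(vann.at[v, "pos"]) - int(prow["pos"])) > probe_overlap_bp
        ]
        if not cand:
            continue
        ph_m = ph.copy()
        ph_m["__m"] = M.values.loc[common, pid].to_numpy(dtype=float)
        spec = ModelSpec(response="__m", covariates=covariates, family="gaussian")
        res = scan_units(
            G.dosages.loc[common, cand], ph_m.reset_index(names="sample_id"), spec
        )
        res = res[res["flag"].isna()].dropna(subset=["beta", "se", "p"])
        res = res.rename(columns={"unit_id": "variant_id"})
        res["probe_id"] = pid
        res["distance"] = [
            int(vann.at[v, "pos"]) - int(prow["pos"]) for v in res["variant_id"]
        ]
        results.append(res[["variant_id", "probe_id", "beta", "se", "p", "n", "distance"]])
    if not results:
        import warnings

        warnings.warn("no variants in any cis window; empty meQTL table")
        return pd.DataFrame(
            columns=["variant_id", "probe_id", "beta", "se", "p", "n", "distance", "q"]
        )
    out = pd.concat(results, ignore_index=True)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


@dataclass
class Clump:
    """A greedy LD clump: index variant plus its r^2-linked members."""

    index_variant: str
    members: list
    index_p: float


def clump(
    assoc: pd.DataFrame,
    G_ref: GenotypeMatrix,
    r2_threshold: float = 0.1,
    p_threshold: float | None = None,
) -> list[Clump]:
    """Greedy LD clumping of one CpG's meQTL associations.

    Sort variants by ascending p (ties: ascending position, then id);
    repeatedly take the best unassigned variant as a clump index and assign
    every unassigned variant with r^2 >= ``r2_threshold`` to it. Clump
    indices are the independent instruments; independence is the strict
    pairwise r^2 < threshold among indices.
    """
    t = assoc.copy()
    if p_threshold is not None:
        t = t[t["p"] <= p_threshold]
    missing = set(t["variant_id"]) - set(G_ref.dosages.columns)
    if missing:
        raise ValueError(f"variants missing from LD reference: {sorted(missing)[:5]}")
    pos = {
        v: int(G_ref.annotation.at[v, "pos"]) if "pos" in G_ref.annotation.columns else 0
        for v in t["variant_id"]
    }
    order = sorted(
        t[["variant_id", "p"]].itertuples(index=False),
        key=lambda r: (r.p, pos[r.variant_id], r.variant_id),
    )
    unassigned = [r.variant_id for r in order]
    pmap = dict(zip(t["variant_id"], t["p"]))
    clumps: list[Clump] = []
    while unassigned:
        index = unassigned.pop(0)
        members = [index]
        rest = []
        for v in unassigned:
            r2 = ld_r2(G_ref, index, v)
            if np.isfinite(r2) and r2 >= r2_threshold:
                members.append(v)
            else:
                rest.append(v)
        unassigned = rest
        clumps.append(Clump(index, members, float(pmap[index])))
    return clumps


def cumulative_f(r2_exposures, n: int) -> float:
    """Cumulative F statistic over a CpG's independent instruments.

    R^2 is the summed marginal variance explained over the (approximately
    independent) clumped instruments; F = ((n - k - 1)/k) * R^2/(1 - R^2)
    with k instruments. F > 10 is the conventional weak-instrument bar.
    """
    r2s = np.asarray(list(r2_exposures), dtype=float)
    k = r2s.size
    if k == 0:
        raise ValueError("no instruments")
    r2 = float(np.sum(r2s))
    if r2 >= 1.0:
        raise ValueError(f"cumulative R^2 >= 1 ({r2:.3f})")
    if r2 < 0:
        raise ValueError("negative R^2")
    return float((n - k - 1) / k * r2 / (1.0 - r2))


_BINARY_CONFOUNDERS = {"sex", "smoker"}
SCREEN_CONFOUNDERS = ("age", "sex", "bmi", "waist", "hip", "smoker")
SCREEN_CONFOUNDERS_RELAXED = ("age", "sex")


def screen_instruments(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    variant_ids,
    confounders=SCREEN_CONFOUNDERS,
    alpha: float = 0.05,
    mode: str = "strict",
):
    """Independence-assumption screen of selected instruments.

    Each instrument is tested for association with each potential confounder
    (simple per-confounder models: OLS for continuous, logistic
    confounder-on-dosage for binary). Any association with p < ``alpha``
    excludes the instrument. ``mode="relaxed"`` screens age and sex only.
    Returns ``(kept ids, exclusion frame with confounder and p)``.
    """
    if mode == "relaxed":
        confounders = SCREEN_CONFOUNDERS_RELAXED
    ph = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    common = [s for s in G.dosages.index if s in ph.index]
    ph = ph.loc[common]
    kept, excluded = [], []
    for vid in variant_ids:
        x = G.dosages.loc[common, vid].to_numpy(dtype=float)
        hit = None
        for conf in confounders:
            if conf not in ph.columns:
                continue
            c = ph[conf]
            if conf in _BINARY_CONFOUNDERS or c.dtype == bool or c.dtype == object:
                y = (
                    c.astype("category").cat.codes.to_numpy(dtype=float)
                    if c.dtype == object
                    else c.to_numpy(dtype=float)
                )
                mask = ~(np.isnan(x) | np.isnan(y))
                if np.ptp(y[mask]) == 0 or np.ptp(x[mask]) == 0:
                    continue
                X = np.column_stack([np.ones(mask.sum()), x[mask]])
                _, _, pvals = _logit(X, y[mask])
                p = float(pvals[1])
            else:
                y = c.to_numpy(dtype=float)
                mask = ~(np.isnan(x) | np.isnan(y))
                if np.ptp(y[mask]) == 0 or np.ptp(x[mask]) == 0:
                    continue
                X = np.column_stack([np.ones(mask.sum()), y[mask]])
                _, _, pvals, _ = _ols(X, x[mask])
                p = float(pvals[1])
            if p < alpha:
                hit = (conf, p)
                break
        if hit is None:
            kept.append(vid)
        else:
            excluded.append({"variant_id": vid, "confounder": hit[0], "p": hit[1]})
    return kept, pd.DataFrame(excluded, columns=["variant_id", "confounder", "p"])


@dataclass
class InstrumentRecord:
    """One independent cis-meQTL instrument for a CpG."""

    variant_id: str
    gamma: float  # SNP -> methylation effect, M-units per alt allele
    se_gamma: float
    p_gamma: float
    r2_exposure: float  # marginal variance in the CpG explained

    def __post_init__(self):
        if self.se_gamma <= 0:
            raise ValueError("se_gamma must be positive")


@dataclass
class InstrumentSet:
    """All admitted instruments for one (CpG, tissue)."""

    cpg: str
    tissue: str
    instruments: list
    cumulative_F: float
    screened: bool = True


def marginal_r2(beta: float, se: float, n: int) -> float:
    """Variance explained from a marginal fit via the t statistic.

    r^2 = t^2 / (t^2 + df) with df = n - 2: the squared (partial)
    correlation implied by the reported effect and SE.
    """
    t2 = (beta / se) ** 2
    df = max(n - 2, 1)
    return float(t2 / (t2 + df))


def joint_r2(M_col: pd.Series, G: GenotypeMatrix, variant_ids) -> float:
    """Joint multi-SNP R^2 from one OLS fit of the CpG on all instruments."""
    common = [s for s in M_col.index if s in G.dosages.index]
    y = M_col.loc[common].to_numpy(dtype=float)
    X = G.dosages.loc[common, list(variant_ids)].to_numpy(dtype=float)
    mask = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[mask], X[mask]
    X = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    return float(1.0 - float(resid @ resid) / tss) if tss > 0 else 0.0


def build_instrument_sets(
    meqtl: pd.DataFrame,
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    tissue: str = "blood",
    fdr_threshold: float = 0.05,
    r2_threshold: float = 0.1,
    screen_mode: str = "strict",
    screen_alpha: float = 0.05,
    min_f: float = 10.0,
    M=None,
    f_mode: str = "marginal",
) -> list[InstrumentSet]:
    """Assemble MR instrument sets from a cis-meQTL scan.

    Per CpG: keep FDR-significant meQTLs, LD-clump them (indices are the
    independent instruments), screen the indices against confounders, sum
    marginal r^2 (or refit jointly with ``f_mode="joint"`` when ``M`` is
    given) into a cumulative F, and admit the set when F > ``min_f``.
    """
    sets: list[InstrumentSet] = []
    sig = meqtl[meqtl["q"] < fdr_threshold]
    for pid, sub in sig.groupby("probe_id", sort=True):
        clumps = clump(sub[["variant_id", "p"]], G, r2_threshold=r2_threshold)
        index_ids = [c.index_variant for c in clumps]
        kept, _ = screen_instruments(
            G, pheno, index_ids, alpha=screen_alpha, mode=screen_mode
        )
        if not kept:
            continue
        rows = sub.set_index("variant_id").loc[kept]
        records = [
            InstrumentRecord(
                variant_id=v,
                gamma=float(r["beta"]),
                se_gamma=float(r["se"]),
                p_gamma=float(r["p"]),
                r2_exposure=marginal_r2(float(r["beta"]), float(r["se"]), int(r["n"])),
            )
            for v, r in rows.iterrows()
        ]
        n_sample = int(rows["n"].max())
        k = len(records)
        if f_mode == "joint" and M is not None:
            r2 = joint_r2(M.values[pid], G, kept)
            if r2 >= 1.0:
                raise ValueError("joint R^2 >= 1")
            f_stat = (n_sample - k - 1) / k * r2 / (1.0 - r2)
        else:
            f_stat = cumulative_f([r.r2_exposure for r in records], n_sample)
        if f_stat > min_f:
            sets.append(InstrumentSet(str(pid), tissue, records, float(f_stat), True))
    return sets


def instrument_sets_to_frame(sets: list[InstrumentSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        for r in s.instruments:
            rows.append(
                {
                    "cpg": s.cpg,
                    "tissue": s.tissue,
                    "variant_id": r.variant_id,
                    "gamma": r.gamma,
                    "se_gamma": r.se_gamma,
                    "p_gamma": r.p_gamma,
                    "r2_exposure": r.r2_exposure,
                    "cumulative_F": s.cumulative_F,
                    "screened": s.screened,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cpg", "tissue", "variant_id", "gamma", "se_gamma", "p_gamma",
            "r2_exposure", "cumulative_F", "screened",
        ],
    )


def instrument_sets_from_frame(frame: pd.DataFrame) -> list[InstrumentSet]:
    sets = []
    for (cpg, tissue), sub in frame.groupby(["cpg", "tissue"], sort=True):
        records = [
            InstrumentRecord(
                r["variant_id"], float(r["gamma"]), float(r["se_gamma"]),
                float(r["p_gamma"]), float(r["r2_exposure"]),
            )
            for _, r in sub.iterrows()
        ]
        sets.append(
            InstrumentSet(
                str(cpg), str(tissue), records,
                float(sub["cumulative_F"].iloc[0]), bool(sub["screened"].iloc[0]),
            )
        )
    return sets
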