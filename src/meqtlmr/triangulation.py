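"""Post hoc triangulation of CpGs flagged causal by MR.

Three complementary lines of evidence:

* temporal stability — per-CpG mean methylation (percent beta) at two time
  points ~6-7 years apart, with a Bland-Altman summary of the per-sample
  differences;
* temporality — baseline methylation across tertiles of follow-up HbA1c,
  compared with a Kruskal-Wallis rank test;
* regulation — cis/trans eQTM mapping of CpG M-values against gene
  expression per tissue, with per-tissue BH-FDR at the strict (<0.05) and
  exploratory (<0.2) tiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import ModelSpec, bh_fdr, beta_from_mvalue, scan_units
from .datamodel import in_window

__all__ = [
    "StabilityRow",
    "stability",
    "tertile_split",
    "kruskal_wallis",
    "eqtm_map",
    "tertile_summary",
]

CIS_WINDOW_BP = 2_000_000  # cis = within 1 Mb of the CpG, i.e. half this span


@dataclass
class StabilityRow:
    """Mean percent methylation of a probe at two time points."""

    probe_id: str
    mean_beta_t1: float
    mean_beta_t2: float
    diff: float  # t2 - t1, percentage points
    mean_of_means: float


def _to_percent_beta(M) -> pd.DataFrame:
    values = M.values if hasattr(M, "scale") else M
    scale = M.scale if hasattr(M, "scale") else "beta_value"
    if scale == "m_value":
        values = pd.DataFrame(
            beta_from_mvalue(values.to_numpy(dtype=float)),
            index=values.index,
            columns=values.columns,
        )
    return values * 100.0


def stability(M_t1, M_t2, probe_ids=None):
    """Per-probe temporal stability over paired samples, on the percent scale.

    Returns ``(rows, bland_altman)``: one :class:`StabilityRow` per probe
    (means over the paired samples at each time point and their difference),
    and a per-probe Bland-Altman frame with the mean per-sample difference
    and 95% limits of agreement (mean +/- 1.96 SD of differences), ready for
    plotting difference against mean-of-means.
    """
    B1, B2 = _to_percent_beta(M_t1), _to_percent_beta(M_t2)
    paired = [s for s in B1.index if s in set(B2.index)]
    if not paired:
        raise ValueError("no paired samples between the two time points")
    probes = [
        p for p in (probe_ids if probe_ids is not None else B1.columns)
        if p in B1.columns and p in B2.columns
    ]
    rows, ba = [], []
    for pid in probes:
        x1 = B1.loc[paired, pid].to_numpy(dtype=float)
        x2 = B2.loc[paired, pid].to_numpy(dtype=float)
        mask = ~(np.isnan(x1) | np.isnan(x2))
        x1, x2 = x1[mask], x2[mask]
        m1, m2 = float(np.mean(x1)), float(np.mean(x2))
        d = x2 - x1
        sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        rows.append(StabilityRow(pid, m1, m2, m2 - m1, (m1 + m2) / 2.0))
        ba.append(
            {
                "probe_id": pid,
                "mean_diff": float(np.mean(d)),
                "loa_low": float(np.mean(d) - 1.96 * sd),
                "loa_high": float(np.mean(d) + 1.96 * sd),
                "n_pairs": int(d.size),
            }
        )
    return rows, pd.DataFrame(ba)


def tertile_split(values) -> np.ndarray:
    """Assign each value to tertile 1/2/3 at the empirical 1/3, 2/3 quantiles.

    Ties on a boundary go to the lower tertile; the groups partition the
    sample and, absent ties, sizes differ by at most one. A degenerate
    all-equal input lands everything in tertile 1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(np.isnan(v)):
        raise ValueError("missing values; drop them before splitting")
    if np.ptp(v) == 0:
        warnings.warn("all values equal; every observation in tertile 1")
        return np.ones(v.size, dtype=int)
    # boundaries from ranks so groups are balanced; ties -> lower tertile
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=int)
    ranks[order] = np.arange(v.size)
    cut1, cut2 = v.size / 3.0, 2.0 * v.size / 3.0
    labels = np.where(ranks < cut1, 1, np.where(ranks < cut2, 2, 3))
    # ties spanning a boundary all take the lower group
    for val in np.unique(v):
        tied = v == val
        if tied.sum() > 1:
            labels[tied] = labels[tied].min()
    return labels


def kruskal_wallis(groups):
    """Kruskal-Wallis rank test across >= 2 non-empty groups.

    Mid-ranks with the standard tie correction; H referred to
    chi-square(g - 1). Invariant under strictly monotone transforms of the
    pooled values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def tertile_summary(methylation_pct, followup_values) -> pd.DataFrame:
    """Median baseline methylation (percent) per follow-up-trait tertile.

    Splits ``followup_values`` into tertiles and summarises the baseline
    methylation of one CpG within each, with the Kruskal-Wallis comparison
    attached as ``attrs['kw_h'] / attrs['kw_p']``.
    """
    m = np.asarray(methylation_pct, dtype=float)
    f = np.asarray(followup_values, dtype=float)
    mask = ~(np.isnan(m) | np.isnan(f))
    m, f = m[mask], f[mask]
    labels = tertile_split(f)
    rows = []
    for t in (1, 2, 3):
        sel = m[labels == t]
        if sel.size == 0:
            continue
        rows.append(
            {
                "tertile": t,
                "n": int(sel.size),
                "median_methylation_pct": float(np.median(sel)),
                "q1": float(np.percentile(sel, 25)),
                "q3": float(np.percentile(sel, 75)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        h, p = kruskal_wallis([m[labels == t] for t in sorted(set(labels))])
        out.attrs["kw_h"], out.attrs["kw_p"] = h, p
    return out


def eqtm_map(
    M,
    expression: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    pheno: pd.DataFrame,
    tissue: str,
    covariates=("age", "sex", "t2d_med_use"),
    probe_ids=None,
    min_n: int = 20,
    cis_window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Expression-on-methylation (eQTM) scan for one tissue.

    Per (probe, gene): OLS of expression on the CpG M-value with age, sex and
    medication-use adjustment. The relation is cis when the gene TSS lies on
    the same chromosome within 1 Mb of the probe, trans otherwise. BH-FDR is
    computed per tissue over all tested pairs; ``significant`` marks
    FDR < 0.05 and ``suggestive`` the exploratory FDR < 0.2 tier.
    """
    values = M.values if hasattr(M, "scale") else M
    ph = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    common = [s for s in expression.index if s in ph.index and s in values.index]
    if len(common) < min_n:
        warnings.warn(
            f"{tissue}: only {len(common)} samples with expression + methylation"
        )
    ph = ph.loc[common]
    covariates = tuple(c for c in covariates if c in ph.columns)
    probes = probe_ids if probe_ids is not None else list(values.columns)
    rows = []
    for pid in probes:
        prow = M.annotation.loc[pid]
        ph_e = ph.copy()
        ph_e["__m"] = values.loc[common, pid].to_numpy(dtype=float)
        spec = ModelSpec(response="", covariates=covariates, family="gaussian")
        # regress each gene's expression on the probe M-value:
        # response varies per gene, so flip roles and scan genes as responses
        for gene in expression.columns:
            y = expression.loc[common, gene].to_numpy(dtype=float)
            x = ph_e["__m"].to_numpy(dtype=float)
            C = _gene_design(ph_e, covariates)
            mask = ~(np.isnan(y) | np.isnan(x) | np.isnan(C).any(axis=1))
            if mask.sum() < C.shape[1] + 7 or np.ptp(x[mask]) == 0:
                continue
            X = np.column_stack([np.ones(mask.sum()), x[mask], C[mask]])
            from .assoc import _ols

            coef, se, pvals, _ = _ols(X, y[mask])
            grow = gene_annotation.loc[gene]
            relation = (
                "cis"
                if str(grow["chrom"]) == str(prow["chrom"])
                and in_window(grow["tss"], prow["pos"], cis_window_bp)
                else "trans"
            )
            rows.append(
                {
                    "probe_id": pid,
                    "gene_id": gene,
                    "tissue": tissue,
                    "beta": float(coef[1]),
                    "se": float(se[1]),
                    "p": float(pvals[1]),
                    "n": int(mask.sum()),
                    "relation": relation,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["probe_id", "gene_id", "tissue", "beta", "se", "p", "n", "relation"],
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < 0.05
        out["suggestive"] = out["q"] < 0.2
    else:
        out["q"] = []
        out["significant"] = []
        out["suggestive"] = []
    return out


def _gene_design(ph: pd.DataFrame, covariates) -> np.ndarray:
    from .assoc import build_design

    C = build_design(ph, covariates)
    return C.to_numpy(dtype=float) if C.shape[1] else np.empty((len(ph), 0))
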