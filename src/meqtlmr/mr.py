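"""Two-sample Mendelian randomisation with Rucker model selection.

Per CpG, the SNP->methylation effects (gamma, se_gamma) from the meQTL
sample are combined with SNP->T2D log-odds effects (Gamma, se_Gamma) from an
independent outcome sample. Estimators:

* Wald ratio (single instrument): theta = Gamma / gamma.
* Fixed-effects IVW: weights w_j = gamma_j^2 / se_Gamma_j^2, equivalent to
  zero-intercept weighted least squares of Gamma on gamma.
* Multiplicative random-effects IVW: same point estimate, SE inflated by
  max(1, sqrt(Q / (J - 1))).
* MR-Egger: weighted regression of Gamma on gamma with a free intercept
  (weights 1/se_Gamma^2); the intercept tests directional pleiotropy and the
  slope is a pleiotropy-robust causal estimate.

Model choice follows the Rucker framework: start from fixed-effects IVW;
when Cochran's Q indicates heterogeneity (p < alpha) move to random-effects
IVW; compute the Rucker Q difference Q_ivw - Q_egger ~ chi-square(1) and,
when it is significant, report MR-Egger. Every computed statistic is kept on
the result regardless of which estimate is selected.

Causal effects are log-odds of T2D per unit M-value; results carry
OR = exp(theta) with 95% CI exp(theta +/- 1.96 se).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeAssoc",
    "MRResult",
    "harmonise",
    "wald_ratio",
    "ivw_fixed",
    "ivw_random",
    "cochran_q",
    "egger",
    "rucker_select",
    "mr_all_cpgs",
]

_Z95 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class OutcomeAssoc:
    """SNP -> outcome association (log-odds of T2D per alt allele)."""

    variant_id: str
    Gamma: float
    se_Gamma: float
    effect_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self):
        if self.se_Gamma <= 0:
            raise ValueError("se_Gamma must be positive")


@dataclass
class MRResult:
    """Causal estimate for one (CpG, tissue) with all heterogeneity statistics."""

    cpg: str
    tissue: str
    method: str  # wald | ivw_fixed | ivw_random | egger
    theta: float
    se_theta: float
    p: float
    n_instruments: int
    cochran_Q: float = np.nan
    cochran_Q_p: float = np.nan
    rucker_Q_diff: float = np.nan
    rucker_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    # every estimator's point estimate, kept for transparency
    theta_ivw_fixed: float = np.nan
    se_ivw_fixed: float = np.nan
    se_ivw_random: float = np.nan
    theta_egger: float = np.nan
    se_egger: float = np.nan
    q_egger: float = np.nan

    @property
    def or_value(self) -> float:
        return float(np.exp(self.theta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.theta - _Z95 * self.se_theta)),
            float(np.exp(self.theta + _Z95 * self.se_theta)),
        )

    def to_dict(self) -> dict:
        d = {
            "cpg": self.cpg,
            "tissue": self.tissue,
            "method": self.method,
            "theta": self.theta,
            "se_theta": self.se_theta,
            "or": self.or_value,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p": self.p,
            "n_instruments": self.n_instruments,
            "cochran_Q": self.cochran_Q,
            "cochran_Q_p": self.cochran_Q_p,
            "rucker_Q_diff": self.rucker_Q_diff,
            "rucker_p": self.rucker_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
        }
        return d


def harmonise(instruments: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Pair exposure and outcome effects on a common effect allele.

    ``instruments`` needs variant_id, gamma, se_gamma (optionally
    effect_allele/other_allele); ``outcome`` needs variant_id, Gamma,
    se_Gamma (same optional allele columns). Pairs whose outcome alleles are
    swapped relative to the exposure have Gamma sign-flipped; irreconcilable
    allele pairs and instruments absent from the outcome table are dropped
    with a warning. Finally every pair is oriented so gamma >= 0 (flip both
    signs), which Egger regression requires and which leaves Wald/IVW
    estimates unchanged.
    """
    out = outcome.set_index("variant_id")
    rows = []
    for _, r in instruments.iterrows():
        vid = r["variant_id"]
        if vid not in out.index:
            warnings.warn(f"instrument {vid} absent from outcome table; dropped")
            continue
        o = out.loc[vid]
        g, G = float(r["gamma"]), float(o["Gamma"])
        if (
            "effect_allele" in r.index
            and "effect_allele" in o.index
            and pd.notna(r.get("effect_allele"))
            and pd.notna(o.get("effect_allele"))
            and r["effect_allele"] != o["effect_allele"]
        ):
            if (
                pd.notna(o.get("other_allele"))
                and o["other_allele"] == r["effect_allele"]
            ):
                G = -G  # same pair of alleles, opposite orientation
            else:
                warnings.warn(f"instrument {vid}: irreconcilable alleles; dropped")
                continue
        if g < 0:
            g, G = -g, -G
        rows.append(
            {
                "variant_id": vid,
                "gamma": g,
                "se_gamma": float(r["se_gamma"]),
                "Gamma": G,
                "se_Gamma": float(o["se_Gamma"]),
            }
        )
    if not rows:
        raise ValueError("no instrument could be paired with the outcome table")
    return pd.DataFrame(rows)


def wald_ratio(
    gamma: float,
    se_gamma: float,
    Gamma: float,
    se_Gamma: float,
    second_order: bool = False,
):
    """Single-instrument causal estimate theta = Gamma / gamma.

    Default SE is the first-order delta approximation se_Gamma/|gamma|; the
    second-order form adds the exposure-uncertainty term
    Gamma^2 se_gamma^2 / gamma^4.
    """
    if gamma == 0:
        raise ValueError("gamma must be nonzero for a Wald ratio")
    theta = Gamma / gamma
    var = se_Gamma**2 / gamma**2
    if second_order:
        var += Gamma**2 * se_gamma**2 / gamma**4
    return float(theta), float(np.sqrt(var))


def _weights(pairs: pd.DataFrame) -> np.ndarray:
    return (pairs["gamma"].to_numpy() ** 2) / (pairs["se_Gamma"].to_numpy() ** 2)


def ivw_fixed(pairs: pd.DataFrame):
    """Fixed-effects IVW estimate over >= 1 harmonised pairs.

    Equals zero-intercept WLS of Gamma on gamma with weights 1/se_Gamma^2;
    a single pair reduces exactly to the Wald ratio.
    """
    J = len(pairs)
    if J == 0:
        raise ValueError("no instrument pairs")
    if J == 1:
        r = pairs.iloc[0]
        return wald_ratio(r["gamma"], r["se_gamma"], r["Gamma"], r["se_Gamma"])
    w = _weights(pairs)
    ratios = pairs["Gamma"].to_numpy() / pairs["gamma"].to_numpy()
    theta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return theta, se


def cochran_q(pairs: pd.DataFrame, theta: float):
    """Cochran's heterogeneity Q over instrument-specific ratios.

    Q = sum w_j (Gamma_j/gamma_j - theta)^2, p from chi-square(J-1).
    """
    w = _weights(pairs)
    ratios = pairs["Gamma"].to_numpy() / pairs["gamma"].to_numpy()
    q = float(np.sum(w * (ratios - theta) ** 2))
    df = len(pairs) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else np.nan
    return q, p


def ivw_random(pairs: pd.DataFrame):
    """Multiplicative random-effects IVW: fixed point estimate, inflated SE.

    The SE is multiplied by max(1, sqrt(Q/(J-1))), so under mild
    heterogeneity it never drops below the fixed-effects SE.
    """
    J = len(pairs)
    if J < 2:
        raise ValueError("random-effects IVW needs >= 2 instruments")
    theta, se_fixed = ivw_fixed(pairs)
    q, _ = cochran_q(pairs, theta)
    scale = max(1.0, np.sqrt(q / (J - 1)))
    return theta, float(se_fixed * scale)


def egger(pairs: pd.DataFrame):
    """MR-Egger: WLS of Gamma on gamma with a free intercept.

    Weights 1/se_Gamma^2; requires J >= 3 and all-positive gamma (the
    harmonised orientation). Returns slope, se_slope, intercept,
    se_intercept, p_intercept, Q_egger (df = J - 2).
    """
    J = len(pairs)
    if J < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    g = pairs["gamma"].to_numpy(dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma must be oriented non-negative (harmonise first)")
    G = pairs["Gamma"].to_numpy(dtype=float)
    w = 1.0 / pairs["se_Gamma"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones(J), g])
    WX = X * w[:, None]
    A = X.T @ WX
    b = X.T @ (w * G)
    coef = np.linalg.solve(A, b)
    resid = G - X @ coef
    q_egger = float(np.sum(w * resid**2))
    cov = np.linalg.inv(A)  # weights are inverse variances: no sigma^2 rescale
    se = np.sqrt(np.diag(cov))
    z_int = coef[0] / se[0]
    p_int = float(2 * stats.norm.sf(abs(z_int)))
    return (
        float(coef[1]),
        float(se[1]),
        float(coef[0]),
        float(se[0]),
        p_int,
        q_egger,
    )


def _norm_p(theta: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(theta / se)))


def rucker_select(
    pairs: pd.DataFrame, cpg: str = "", tissue: str = "blood", alpha: float = 0.05
) -> MRResult:
    """Rucker-framework model selection for one CpG.

    1. J = 1: Wald ratio.
    2. Fit fixed-effects IVW and Cochran's Q; Q p >= alpha -> report IVW
       fixed effects.
    3. Otherwise fit random-effects IVW. With J >= 3, compute the Rucker Q
       difference Q_ivw - Q_egger against chi-square(1): significant ->
       report MR-Egger, else report random-effects IVW. With J = 2 the
       transition test is unavailable and random-effects IVW is reported.

    All computed statistics are retained on the result whichever method is
    selected.
    """
    J = len(pairs)
    if J == 0:
        raise ValueError("no instrument pairs")
    if J == 1:
        r = pairs.iloc[0]
        theta, se = wald_ratio(r["gamma"], r["se_gamma"], r["Gamma"], r["se_Gamma"])
        return MRResult(
            cpg, tissue, "wald", theta, se, _norm_p(theta, se), 1,
            theta_ivw_fixed=theta, se_ivw_fixed=se,
        )
    theta_f, se_f = ivw_fixed(pairs)
    q, q_p = cochran_q(pairs, theta_f)
    res = MRResult(
        cpg, tissue, "ivw_fixed", theta_f, se_f, _norm_p(theta_f, se_f), J,
        cochran_Q=q, cochran_Q_p=q_p, theta_ivw_fixed=theta_f, se_ivw_fixed=se_f,
    )
    if J >= 3:
        slope, se_slope, intercept, se_int, p_int, q_egger = egger(pairs)
        res.theta_egger, res.se_egger, res.q_egger = slope, se_slope, q_egger
        res.egger_intercept, res.egger_intercept_se = intercept, se_int
        res.egger_intercept_p = p_int
        res.rucker_Q_diff = q - q_egger
        res.rucker_p = float(stats.chi2.sf(max(q - q_egger, 0.0), 1))
    if q_p >= alpha:
        return res
    _, se_r = ivw_random(pairs)
    res.se_ivw_random = se_r
    res.method, res.se_theta = "ivw_random", se_r
    res.p = _norm_p(res.theta, se_r)
    if J >= 3 and res.rucker_p < alpha:
        res.method = "egger"
        res.theta, res.se_theta = res.theta_egger, res.se_egger
        res.p = _norm_p(res.theta, res.se_theta)
    return res


def mr_all_cpgs(
    instrument_sets, outcome: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Run Rucker-selected MR for every (CpG, tissue) instrument set.

    ``outcome`` is a frame with variant_id, Gamma, se_Gamma (an AssocTable
    from the outcome GWAS works via ``outcome_assoc_from_table``). CpGs whose
    instruments cannot be paired with the outcome are omitted with a warning.
    Adds a BH-FDR column over the selected-method p-values for transparency;
    interpretation in this framework is at nominal p.
    """
    from .assoc import bh_fdr
    from .instruments import instrument_sets_to_frame

    if not isinstance(instrument_sets, list):
        instrument_sets = [instrument_sets]
    results = []
    for s in instrument_sets:
        frame = instrument_sets_to_frame([s])
        try:
            pairs = harmonise(frame, outcome)
        except ValueError:
            warnings.warn(f"CpG {s.cpg}: no usable instruments; omitted")
            continue
        results.append(rucker_select(pairs, cpg=s.cpg, tissue=s.tissue, alpha=alpha))
    if not results:
        return pd.DataFrame()
    table = pd.DataFrame([r.to_dict() for r in results])
    table["q_bh"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


def outcome_assoc_from_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Adapt a canonical AssocTable (variant rows) to the outcome format."""
    return pd.DataFrame(
        {
            "variant_id": assoc["unit_id"],
            "Gamma": assoc["beta"],
            "se_Gamma": assoc["se"],
        }
    )
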