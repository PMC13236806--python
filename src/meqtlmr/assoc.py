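"""Covariate-adjusted association machinery shared by every stage.

EWAS (methylation ~ trait), SNP-outcome GWAS, genomic-inflation diagnostics,
Benjamini-Hochberg FDR and inverse-variance fixed-effects meta-analysis.

All model fits are complete-case per unit. Gaussian fits are ordinary least
squares; the binary outcome is fitted either as maximum-likelihood logistic
regression (log-odds scale, the default for the outcome GWAS) or as a linear
model on the 0/1 label ("gaussian-on-binary", the default for the T2D EWAS,
which mirrors the common linear-on-binary EWAS convention).

The epigenome-wide scans use the Frisch-Waugh-Lovell decomposition: the
response and every probe column are residualised on the covariate design once,
after which each per-probe slope, SE and p-value is exact OLS at a fraction of
the cost of refitting the full design per probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ASSOC_COLUMNS, CELL_TYPES, validate_assoc_table

__all__ = [
    "ModelSpec",
    "UnitFit",
    "mvalue_from_beta",
    "beta_from_mvalue",
    "fit_unit_association",
    "run_ewas",
    "run_outcome_gwas",
    "genomic_lambda",
    "bh_fdr",
    "meta_fixed",
]

#: Expected null median of a 1-df chi-square statistic.
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

_BETA_CLIP = 1e-6


def mvalue_from_beta(beta, clip: float = _BETA_CLIP):
    """M = log2(beta / (1 - beta)).

    Beta-values are methylation fractions in [0, 1]; values are clipped to
    [clip, 1 - clip] before the logit so boundary betas do not map to +/-inf.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b[np.isfinite(b)] < 0) | (b[np.isfinite(b)] > 1)):
        raise ValueError("beta-value outside [0, 1]")
    b = np.clip(b, clip, 1.0 - clip)
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def beta_from_mvalue(m):
    """Inverse of :func:`mvalue_from_beta`: beta = 2^M / (2^M + 1)."""
    m_arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m_arr))
    return float(out) if np.isscalar(m) else out


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    response : trait column name in the phenotype table.
    transform : "identity" or "log" (natural log; requires positive response).
    covariates : phenotype columns entering the design. When all six cell
        proportions are listed, the neutrophil column is dropped before
        fitting: the fractions are compositional (sum to one) and keeping all
        six makes the design rank-deficient.
    family : "gaussian", "binomial-logit" or "gaussian-on-binary".
    """

    response: str
    covariates: tuple = ()
    transform: str = "identity"
    family: str = "gaussian"

    def __post_init__(self):
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.family not in ("gaussian", "binomial-logit", "gaussian-on-binary"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class UnitFit:
    beta: float
    se: float
    p: float
    n: int
    flag: str | None = None


_CATEGORICAL = {"site", "plate", "plate_position", "sex"}


def build_design(pheno: pd.DataFrame, covariates) -> pd.DataFrame:
    """Build the numeric covariate design (no intercept column).

    Categorical columns are dummy-coded with the first level as reference;
    booleans become 0/1; the neutrophil fraction is dropped when all six
    cell-proportion columns are requested (compositional redundancy).
    """
    covariates = list(covariates)
    missing = [c for c in covariates if c not in pheno.columns]
    if missing:
        raise ValueError(f"covariates missing from phenotype table: {missing}")
    if all(ct in covariates for ct in CELL_TYPES):
        covariates = [c for c in covariates if c != "neu"]
    parts = []
    for col in covariates:
        s = pheno[col]
        if col in _CATEGORICAL or s.dtype == object or isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            d = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True)
            parts.append(d.astype(float))
        elif s.dtype == bool:
            parts.append(s.astype(float).to_frame(col))
        else:
            parts.append(s.astype(float).to_frame(col))
    if not parts:
        return pd.DataFrame(index=pheno.index)
    return pd.concat(parts, axis=1)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity for the error message
        bad = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS coefficients, SEs and two-sided t p-values."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - k
    if df <= 0:
        raise ValueError("not enough observations for the design")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return coef, se, p, df


def _logit(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit via statsmodels; Wald z p-values."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    return np.asarray(res.params), np.asarray(res.bse), np.asarray(res.pvalues)


def _prepare_response(pheno: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    y = pheno[spec.response].astype(float)
    if spec.transform == "log":
        y = y.where(y > 0)  # non-positive responses become missing
        y = np.log(y)
    return y


def fit_unit_association(
    predictor: pd.Series, pheno: pd.DataFrame, spec: ModelSpec
) -> UnitFit:
    """Fit ``response ~ predictor + covariates`` for one probe or variant.

    ``predictor`` must be indexed by sample id; ``pheno`` must carry a
    ``sample_id`` column. Complete-case on response, predictor and
    covariates. Returns the predictor's effect, SE, two-sided p and the
    number of samples used. A zero-variance predictor is skipped with a flag
    rather than raised.
    """
    ph = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    y = _prepare_response(ph, spec)
    C = build_design(ph, spec.covariates)
    x = predictor.reindex(ph.index).astype(float)
    frame = pd.concat([y.rename("__y"), x.rename("__x"), C], axis=1).dropna()
    n = len(frame)
    k_params = frame.shape[1] + 1  # + intercept
    if n < k_params + 5:
        raise ValueError(f"too few complete cases ({n}) for {k_params} parameters")
    xv = frame["__x"].to_numpy()
    if np.ptp(xv) == 0.0:
        return UnitFit(np.nan, np.nan, np.nan, n, flag="zero_variance_predictor")
    X = np.column_stack([np.ones(n), xv, frame.drop(columns=["__y", "__x"]).to_numpy(float)])
    names = ["intercept", "__x"] + list(frame.columns[2:])
    _check_rank(X, names)
    yv = frame["__y"].to_numpy()
    if spec.family == "binomial-logit":
        classes = np.unique(yv)
        if classes.size < 2:
            raise ValueError("binary response has a single class after exclusions")
        coef, se, p = _logit(X, yv)
    else:
        coef, se, p, _ = _ols(X, yv)
    return UnitFit(float(coef[1]), float(se[1]), float(p[1]), n)


def _fwl_scan(Y: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Per-column OLS of ``y`` on each column of ``Y`` plus covariates ``C``.

    Frisch-Waugh-Lovell: residualise y and every column of Y on [1, C], then
    each simple-regression slope of the residuals equals the full-model OLS
    slope, with df = n - q - 1 where q = 1 + C.shape[1]. Requires complete
    data (the caller handles columns with missing values separately).
    """
    n = y.shape[0]
    D = np.column_stack([np.ones(n), C]) if C.size else np.ones((n, 1))
    q = D.shape[1]
    coef_y, *_ = np.linalg.lstsq(D, y, rcond=None)
    ry = y - D @ coef_y
    coef_Y, *_ = np.linalg.lstsq(D, Y, rcond=None)
    RY = Y - D @ coef_Y
    sxx = np.einsum("ij,ij->j", RY, RY)
    sxy = RY.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
    df = n - q - 1
    ssr = float(ry @ ry) - beta**2 * sxx
    sigma2 = np.maximum(ssr, 0.0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, p, df


def scan_units(
    units: pd.DataFrame, pheno: pd.DataFrame, spec: ModelSpec
) -> pd.DataFrame:
    """Association scan of one response against every column of ``units``.

    Vectorised for columns without missing values; per-column complete-case
    fits otherwise. Zero-variance columns are flagged and skipped. Returns a
    frame with unit_id, beta, se, p, n, flag.
    """
    if spec.family == "binomial-logit":
        rows = []
        for uid in units.columns:
            fit = fit_unit_association(units[uid], pheno, spec)
            rows.append((uid, fit.beta, fit.se, fit.p, fit.n, fit.flag))
        return pd.DataFrame(rows, columns=["unit_id", "beta", "se", "p", "n", "flag"])

    ph = pheno.set_index("sample_id") if "sample_id" in pheno.columns else pheno
    y = _prepare_response(ph, spec)
    C = build_design(ph, spec.covariates)
    U = units.reindex(ph.index)
    base = pd.concat([y.rename("__y"), C], axis=1)
    keep = base.notna().all(axis=1)
    base, U = base[keep], U[keep]
    nbase = len(base)
    if nbase < C.shape[1] + 7:
        raise ValueError("too few complete cases for the covariate design")
    yv = base["__y"].to_numpy()
    Cv = base.drop(columns="__y").to_numpy(float)
    _check_rank(np.column_stack([np.ones(nbase), Cv]), ["intercept"] + list(C.columns))

    out = pd.DataFrame(
        index=U.columns,
        data={"beta": np.nan, "se": np.nan, "p": np.nan, "n": 0, "flag": None},
    )
    Uv = U.to_numpy(float)
    complete = ~np.isnan(Uv).any(axis=0)
    variable = np.ptp(np.nan_to_num(Uv), axis=0) > 0
    fast = complete & variable
    if fast.any():
        beta, se, p, _ = _fwl_scan(Uv[:, fast], yv, Cv)
        out.loc[fast, ["beta", "se", "p"]] = np.column_stack([beta, se, p])
        out.loc[fast, "n"] = nbase
    for j in np.where(~complete)[0]:
        mask = ~np.isnan(Uv[:, j])
        xj = Uv[mask, j]
        out.iloc[j, out.columns.get_loc("n")] = int(mask.sum())
        if np.ptp(xj) == 0:
            out.iloc[j, out.columns.get_loc("flag")] = "zero_variance_predictor"
            continue
        b, s, pv, _ = _fwl_scan(xj[:, None], yv[mask], Cv[mask])
        out.iloc[j, [0, 1, 2]] = [b[0], s[0], pv[0]]
    out.loc[complete & ~variable, "flag"] = "zero_variance_predictor"
    out.loc[complete & ~variable, "n"] = nbase
    return out.rename_axis("unit_id").reset_index()


def run_ewas(
    M,
    pheno: pd.DataFrame,
    spec: ModelSpec,
    trait: str | None = None,
    cohort: str = "cohort",
    exclude_medicated: bool = True,
) -> pd.DataFrame:
    """Epigenome-wide scan of a trait against every probe.

    Participants on glucose-lowering medication are excluded before fitting
    (methylation is strongly perturbed by these drugs). For a binary trait
    the default family regresses the 0/1 case label on methylation
    ("gaussian-on-binary"); pass ``family="binomial-logit"`` in the spec for
    logistic. The genomic inflation factor of the scan is attached as
    ``result.attrs["lambda"]``.
    """
    values = M.values if hasattr(M, "values") and hasattr(M, "scale") else M
    ph = pheno.copy()
    if exclude_medicated and "t2d_med_use" in ph.columns:
        ph = ph[~ph["t2d_med_use"].fillna(False).astype(bool)]
    if spec.family in ("binomial-logit", "gaussian-on-binary"):
        cls = ph[spec.response].dropna().unique()
        if len(cls) < 2:
            raise ValueError("fewer than two phenotype classes after exclusions")
    res = scan_units(values, ph, spec)
    fitted = res[res["flag"].isna()] if res["flag"].notna().any() else res
    table = pd.DataFrame(
        {
            "unit_id": fitted["unit_id"],
            "beta": fitted["beta"],
            "se": fitted["se"],
            "p": fitted["p"],
            "n": fitted["n"].astype(int),
            "trait": trait or spec.response,
            "cohort": cohort,
        }
    )
    table = validate_assoc_table(table.dropna(subset=["beta", "se", "p"]))
    table.attrs["lambda"] = (
        genomic_lambda(table["p"].to_numpy()) if len(table) else np.nan
    )
    table.attrs["flagged"] = res.loc[res["flag"].notna(), "unit_id"].tolist()
    return table


def run_outcome_gwas(
    G,
    pheno: pd.DataFrame,
    spec: ModelSpec | None = None,
    cohort: str = "outcome",
    exposure_sample_ids=None,
) -> pd.DataFrame:
    """SNP -> outcome association scan for the MR outcome side.

    Two-sample MR requires the outcome sample to be disjoint from the
    exposure (meQTL) sample; overlap by sample id is a hard error.
    Default model: logistic regression of T2D on dosage with age, sex, the
    leading genotype principal components and BMI.
    """
    if spec is None:
        spec = ModelSpec(
            response="t2d_status",
            covariates=("age", "sex", "pc1", "pc2", "pc3", "bmi"),
            family="binomial-logit",
        )
    if exposure_sample_ids is not None:
        overlap = set(pheno["sample_id"]) & set(exposure_sample_ids)
        if overlap:
            raise ValueError(
                f"outcome sample overlaps exposure sample: {sorted(overlap)[:5]}"
            )
    dosages = G.dosages if hasattr(G, "dosages") else G
    res = scan_units(dosages, pheno, spec)
    fitted = res[res["flag"].isna()].dropna(subset=["beta", "se", "p"])
    return validate_assoc_table(
        pd.DataFrame(
            {
                "unit_id": fitted["unit_id"],
                "beta": fitted["beta"],
                "se": fitted["se"],
                "p": fitted["p"],
                "n": fitted["n"].astype(int),
                "trait": spec.response,
                "cohort": cohort,
            }
        )
    )


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median observed 1-df chi-square / 0.4549.

    Values near 1 indicate well-calibrated test statistics; inflation above
    ~1.1 suggests confounding or model misfit.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.asarray([], dtype=float)
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def meta_fixed(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effects meta-analysis across cohorts.

    For each unit present in at least one cohort: w_c = 1/se_c^2,
    beta = sum(w_c beta_c)/sum(w_c), se = sum(w_c)^(-1/2), two-sided normal
    p, plus Cochran's Q across cohorts (df = #cohorts with the unit - 1) and
    a per-cohort direction string (+/-/? in input cohort order).
    """
    tables = [validate_assoc_table(t) for t in tables]
    k = len(tables)
    if k == 0:
        raise ValueError("no cohorts to meta-analyse")
    units: list[str] = []
    seen = set()
    for t in tables:
        for u in t["unit_id"]:
            if u not in seen:
                seen.add(u)
                units.append(u)
    maps = [t.set_index("unit_id") for t in tables]
    rows = []
    for u in units:
        betas, ses, ns, direction = [], [], [], []
        for m in maps:
            if u in m.index:
                r = m.loc[u]
                betas.append(float(r["beta"]))
                ses.append(float(r["se"]))
                ns.append(int(r["n"]))
                direction.append("+" if r["beta"] > 0 else ("-" if r["beta"] < 0 else "0"))
            else:
                direction.append("?")
        b = np.asarray(betas)
        w = 1.0 / np.asarray(ses) ** 2
        beta_meta = float(np.sum(w * b) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        z = beta_meta / se_meta
        q = float(np.sum(w * (b - beta_meta) ** 2))
        dfq = len(b) - 1
        q_p = float(stats.chi2.sf(q, dfq)) if dfq > 0 else np.nan
        rows.append(
            {
                "unit_id": u,
                "beta_meta": beta_meta,
                "se_meta": se_meta,
                "p_meta": float(2 * stats.norm.sf(abs(z))),
                "n_total": int(np.sum(ns)),
                "direction": "".join(direction),
                "cochran_q_meta": q,
                "q_p": q_p,
            }
        )
    return pd.DataFrame(rows)


def meta_to_assoc(meta: pd.DataFrame, trait: str, cohort: str = "meta") -> pd.DataFrame:
    """Project a meta-analysis result back onto the canonical AssocTable."""
    return validate_assoc_table(
        pd.DataFrame(
            {
                "unit_id": meta["unit_id"],
                "beta": meta["beta_meta"],
                "se": meta["se_meta"],
                "p": meta["p_meta"],
                "n": meta["n_total"],
                "trait": trait,
                "cohort": cohort,
            }
        )
    )
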