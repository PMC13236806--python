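"""Shared domain types for methylation, genotype and association data.

Coordinate convention: all positions are 1-based and inclusive, matching VCF.
Window arithmetic throughout the package is done against this convention via
:func:`in_window`.

Matrices are carried as pandas DataFrames (samples in rows, units in columns)
wrapped in light containers that validate the invariants the downstream
statistics rely on: beta-values in [0, 1], dosages in [0, 2], unique ids,
dimensions consistent with the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpgProbe",
    "Variant",
    "MethylationMatrix",
    "GenotypeMatrix",
    "ASSOC_COLUMNS",
    "CELL_TYPES",
    "validate_assoc_table",
    "validate_pheno_table",
    "in_window",
]

#: The six Houseman-style leukocyte fractions carried as covariates.
CELL_TYPES = ["cd8t", "cd4t", "nk", "b", "mono", "neu"]

#: Canonical column order for association summary-statistic tables.
ASSOC_COLUMNS = ["unit_id", "beta", "se", "p", "n", "trait", "cohort"]


@dataclass(frozen=True)
class CpgProbe:
    """A methylation array probe: one interrogated cytosine.

    ``pos`` is the 1-based coordinate of the interrogated CpG.
    """

    probe_id: str
    chrom: str
    pos: int
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe {self.probe_id}: pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class Variant:
    """A biallelic genetic variant with per-marker QC metrics."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    alt_freq: float = np.nan
    info_score: float = 1.0
    call_rate: float = 1.0
    hwe_p: float = 1.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.variant_id}: pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.variant_id}: ref and alt alleles are equal")
        if np.isfinite(self.alt_freq) and not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"variant {self.variant_id}: alt_freq outside [0, 1]")


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what} ids: {dups[:5]}")


@dataclass
class MethylationMatrix:
    """Samples x probes methylation matrix on the M or beta scale.

    ``values``: DataFrame indexed by sample id with probe-id columns.
    ``annotation``: DataFrame indexed by probe_id with columns
    ``chrom``, ``pos`` and optionally ``gene_label``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    scale: str = "m_value"
    time_point: int = 1

    def __post_init__(self) -> None:
        if self.scale not in ("m_value", "beta_value"):
            raise ValueError(f"unknown methylation scale {self.scale!r}")
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "probe")
        missing = self.values.columns.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"probes missing from annotation: {list(missing[:5])}")
        if self.scale == "beta_value":
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("beta-values outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    def probes(self) -> list[CpgProbe]:
        ann = self.annotation.loc[self.probe_ids]
        return [
            CpgProbe(pid, str(row["chrom"]), int(row["pos"]), row.get("gene_label"))
            for pid, row in ann.iterrows()
        ]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix (alt-allele counts in [0, 2])."""

    dosages: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "sample")
        _check_unique(self.dosages.columns, "variant")
        missing = self.dosages.columns.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"variants missing from annotation: {list(missing[:5])}")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            bad = float(finite[(finite < 0) | (finite > 2)][0])
            raise ValueError(f"dosage out of [0,2]: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        keep = [v for v in self.dosages.columns if v in set(variant_ids)]
        return GenotypeMatrix(self.dosages[keep], self.annotation.loc[keep])


def validate_assoc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise an association summary-statistics table."""
    missing = [c for c in ASSOC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    t = table[ASSOC_COLUMNS].copy()
    se = t["se"].to_numpy(dtype=float)
    if np.any(se[np.isfinite(se)] <= 0):
        raise ValueError("association table has se <= 0")
    p = t["p"].to_numpy(dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("association table has p outside [0, 1]")
    n = t["n"].to_numpy()
    if np.any(pd.notna(n) & (n < 1)):
        raise ValueError("association table has n < 1")
    return t


# Phenotype/covariate table columns that must be numeric when present.
_PHENO_NUMERIC = [
    "age", "bmi", "waist", "hip", "fasting_glucose", "insulin", "hba1c",
    "homa_s", "homa_b", "hba1c_followup", "ancestry_fraction",
] + CELL_TYPES


def validate_pheno_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Light validation of a phenotype/covariate table.

    Requires a ``sample_id`` column with unique ids; checks cell proportions
    lie in [0, 1] and age is non-negative where present. Missing values stay
    as NaN — every model fit downstream is complete-case per analysis.
    """
    if "sample_id" not in pheno.columns:
        raise ValueError("phenotype table must have a sample_id column")
    _check_unique(pheno["sample_id"], "sample")
    for col in CELL_TYPES:
        if col in pheno.columns:
            v = pheno[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError(f"cell proportion {col} outside [0, 1]")
    if "age" in pheno.columns:
        a = pheno["age"].to_numpy(dtype=float)
        if np.any(a[np.isfinite(a)] < 0):
            raise ValueError("negative age")
    return pheno


def in_window(pos_a: int, pos_b: int, window_bp: int) -> bool:
    """True when two 1-based positions are within ``window_bp/2`` of each other.

    A "2 Mb region around" a site is interpreted as +/-1 Mb; the same utility
    backs the cis-meQTL window, the clumping radius, and the cis/trans eQTM
    classification so the arithmetic cannot drift apart.
    """
    return abs(int(pos_a) - int(pos_b)) <= window_bp // 2
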