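"""Readers and writers for the tab-delimited interchange formats.

Every matrix is written with a header row of sample ids and unit ids in the
first column (units in rows on disk, transposed to samples x units in
memory). Missing values are encoded ``NA``. All writers and readers
round-trip: ``read(write(x)) == x`` up to float representation, which is kept
exact by writing floats with ``repr`` precision.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import (
    ASSOC_COLUMNS,
    GenotypeMatrix,
    MethylationMatrix,
    validate_assoc_table,
    validate_pheno_table,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_assoc_table",
    "write_assoc_table",
    "read_pheno",
    "write_pheno",
    "read_vcf_dosages",
]

_NA = "NA"


def _read_tsv_matrix(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicated sample ids")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA],
                     keep_default_na=False, float_precision="round_trip")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicated unit ids")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric cell at row {bad.index[0]!r}, column {col!r}"
            )
    # on disk: units x samples; in memory: samples x units
    return df.T.astype(float)


def read_annotation(path: str) -> pd.DataFrame:
    """Read a probe/variant/gene annotation table indexed by its first column."""
    ann = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    if ann.index.has_duplicates:
        raise ValueError(f"{path}: duplicated annotation ids")
    return ann


def write_annotation(ann: pd.DataFrame, path: str) -> None:
    ann.to_csv(path, sep="\t", na_rep=_NA)


def read_matrix(
    path: str,
    kind: str,
    annotation: str | pd.DataFrame | None = None,
    scale: str = "m_value",
    time_point: int = 1,
):
    """Read a methylation, genotype or expression matrix.

    Parameters
    ----------
    kind : {"methylation", "genotype", "expression"}
    annotation : sidecar annotation file (or frame) joined onto the result.
        Required for methylation and genotype matrices.
    scale : methylation scale declared for the file ("m_value"/"beta_value").
    """
    values = _read_tsv_matrix(path)
    if isinstance(annotation, str):
        annotation = read_annotation(annotation)
    if kind == "methylation":
        if annotation is None:
            raise ValueError("methylation matrix requires a probe annotation")
        return MethylationMatrix(values, annotation, scale=scale, time_point=time_point)
    if kind == "genotype":
        if annotation is None:
            raise ValueError("genotype matrix requires a variant annotation")
        return GenotypeMatrix(values, annotation)
    if kind == "expression":
        return values if annotation is None else (values, annotation)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(obj, path: str) -> None:
    """Write a matrix container (or plain samples x units frame) to TSV."""
    values = obj.values if isinstance(obj, MethylationMatrix) else (
        obj.dosages if isinstance(obj, GenotypeMatrix) else obj
    )
    values.T.to_csv(path, sep="\t", na_rep=_NA)


def write_assoc_table(table: pd.DataFrame, path: str) -> None:
    """Write an association table with the fixed canonical column order.

    Floats are written at full ``repr`` precision so extreme p-values
    (e.g. 1.6e-300) survive the round trip exactly.
    """
    t = validate_assoc_table(table)
    t.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_assoc_table(path: str) -> pd.DataFrame:
    t = pd.read_csv(
        path, sep="\t", na_values=[_NA], keep_default_na=False,
        dtype={"unit_id": str, "trait": str, "cohort": str},
        float_precision="round_trip",
    )
    if list(t.columns) != ASSOC_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {list(t.columns)}")
    return validate_assoc_table(t)


def write_pheno(pheno: pd.DataFrame, path: str) -> None:
    validate_pheno_table(pheno).to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_pheno(path: str) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    return validate_pheno_table(pheno)


def read_vcf_dosages(path: str) -> GenotypeMatrix:
    """Optional VCF input path: read a VCF (v4.x) into a GenotypeMatrix.

    Uses the DS FORMAT field when present, otherwise the alt-allele count from
    GT. INFO fields AF and INFO/R2 populate alt_freq and info_score when
    available. Requires ``cyvcf2``; delimited text remains the canonical
    interchange format.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires cyvcf2") from exc

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, ann_rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # biallelic only
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        try:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        except (TypeError, KeyError, ValueError):
            gts = np.asarray(rec.gt_types, dtype=float)  # 0,1,3 -> 0,1,2; 2=unknown
            ds = np.where(gts == 2, np.nan, np.where(gts == 3, 2.0, gts))
        rows.append(ds)
        info = dict(rec.INFO) if rec.INFO is not None else {}
        ann_rows.append(
            {
                "variant_id": vid,
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref_allele": rec.REF,
                "alt_allele": rec.ALT[0],
                "alt_freq": float(info.get("AF", np.nan)),
                "info_score": float(info.get("R2", info.get("INFO", 1.0))),
                "call_rate": 1.0 - float(np.mean(np.isnan(ds))),
                "hwe_p": 1.0,
            }
        )
    ann = pd.DataFrame(ann_rows).set_index("variant_id")
    dosages = pd.DataFrame(np.asarray(rows).T, index=samples, columns=ann.index)
    return GenotypeMatrix(dosages, ann)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
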