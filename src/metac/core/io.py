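"""Tab-separated file I/O for every format the pipeline touches.

Dialects (all plain TSV with a header row):

* expression: first column gene ids, remaining columns one per sample;
* GMT: ``name<TAB>description<TAB>gene...`` one set per line;
* annotation: ``sample_id``, ``patient_id``, ``timepoint_id``,
  ``treatment_state``, ``metastatic_site``, ``survival_time``, ``event``
  plus arbitrary extra covariate columns;
* variants: ``sample_id``, ``gene``, ``effect_class``,
  ``sift_deleterious``, ``polyphen_damaging``;
* copy number: ``sample_id``, ``gene``, ``copy_number``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from metac.core.types import ExpressionMatrix, GeneSet, SampleAnnotation, SignatureMatrix

log = logging.getLogger(__name__)


def read_expression(path, scale: str) -> ExpressionMatrix:
    """Read a genes x samples expression TSV with a declared scale.

    Duplicate gene rows are collapsed by their mean (logged); duplicate
    sample columns are an error; a non-numeric cell raises a parse error
    naming its row and column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{path}: duplicated sample ids {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    if numeric.index.duplicated().any():
        dupes = numeric.index[numeric.index.duplicated()].unique().tolist()
        log.warning("%s: collapsing duplicated gene rows by mean: %s", path, dupes[:10])
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric, scale)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_signature(path, scale: str) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(df, scale)


def write_signature(sig: SignatureMatrix, path) -> None:
    sig.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set file; order of lines is preserved."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(fields[0], fields[1], genes))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="sample_id")


_VARIANT_COLS = ["sample_id", "gene", "effect_class", "sift_deleterious", "polyphen_damaging"]
_CNV_COLS = ["sample_id", "gene", "copy_number"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_variants(path) -> pd.DataFrame:
    """Read a gene-level variant table (one row per sample/gene/variant)."""
    df = _read_table(path, _VARIANT_COLS[:3])
    for col in ("sift_deleterious", "polyphen_damaging"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = df[col].map(
            lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else
            (None if pd.isna(v) else str(v).strip().lower() in ("true", "1", "yes"))
        )
    return df[_VARIANT_COLS]


def write_variants(df: pd.DataFrame, path) -> None:
    df[_VARIANT_COLS].to_csv(path, sep="\t", index=False)


def read_cnv(path) -> pd.DataFrame:
    """Read a gene-level copy-number table (integer copy numbers)."""
    df = _read_table(path, _CNV_COLS)
    df["copy_number"] = df["copy_number"].astype(int)
    if (df["copy_number"] < 0).any():
        raise ValueError(f"{path}: negative copy numbers")
    return df[_CNV_COLS]


def write_cnv(df: pd.DataFrame, path) -> None:
    df[_CNV_COLS].to_csv(path, sep="\t", index=False)


def write_fractions(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="sample_id")


def read_fractions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_gene_list(path) -> list[str]:
    """Read a one-gene-per-line list (optionally with a subtype column)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
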