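"""Delimited-text readers and writers for cohort tables and result frames.

Conventions: samples in rows, features in columns, header row of feature
ids, first column of sample ids.  Missing values are accepted as empty
cells or the token ``NA`` and always written back as empty cells.  ``.csv``
paths are comma-separated, everything else tab-separated.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    FeatureAnnotation,
    PhenotypeTable,
    SampleMeta,
    ValidationError,
    validate_cohort,
)

_NA_TOKENS = ["", "NA"]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0,
        na_values=_NA_TOKENS, keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_abundance(path, meta_path, annot_path=None):
    """Read an abundance matrix plus sample metadata (and annotation).

    Returns ``(AbundanceTable, SampleMeta, FeatureAnnotation | None)``.
    The matrix needs a per-feature ``platform`` row in the annotation file,
    or a ``platform`` column there; samples present in the matrix but absent
    from the metadata (or vice versa) raise :class:`ValidationError`.
    """
    mat = _read_matrix(path)
    meta = read_sample_meta(meta_path)
    annot = read_annotation(annot_path) if annot_path is not None else None
    if annot is not None and "platform" in annot.frame.columns:
        platform = annot.frame["platform"].reindex(mat.columns)
    else:
        raise ValidationError("feature annotation with a 'platform' column is required")
    table = AbundanceTable(mat, platform)
    validate_cohort(table, meta)
    return table, meta, annot


def read_sample_meta(path) -> SampleMeta:
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0,
        na_values=_NA_TOKENS, keep_default_na=False, dtype=str,
    )
    if "body_weight" in df.columns:
        df["body_weight"] = pd.to_numeric(df["body_weight"], errors="raise")
    return SampleMeta(df)


def read_annotation(path) -> FeatureAnnotation:
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0,
        na_values=_NA_TOKENS, keep_default_na=False, dtype=str,
    )
    return FeatureAnnotation(df)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(_read_matrix(path))


def _write_frame(df: pd.DataFrame, path, index_label) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep=_sep(path), na_rep="", index_label=index_label,
              float_format="%.12g", lineterminator="\n")


def write_abundance(table: AbundanceTable, path) -> None:
    _write_frame(table.data, path, index_label="sample_id")


def write_sample_meta(meta: SampleMeta, path) -> None:
    _write_frame(meta.frame, path, index_label="sample_id")


def write_annotation(annot: FeatureAnnotation, path) -> None:
    _write_frame(annot.frame, path, index_label="feature_id")


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    _write_frame(pheno.data, path, index_label="sample_id")


def write_table(result_rows, path, sort_by=None) -> None:
    """Write homogeneous result records as a deterministic TSV.

    Accepts a DataFrame or an iterable of dicts.  Rows are sorted by
    ``sort_by`` (default: ``feature_id`` then ``ko_line`` where present) so
    two writes of the same records are byte-identical; p-values survive a
    round-trip to at least 12 significant digits.
    """
    if isinstance(result_rows, pd.DataFrame):
        df = result_rows.copy()
    else:
        df = pd.DataFrame(list(result_rows))
    if sort_by is None:
        sort_by = [c for c in ("feature_id", "ko_line", "phenotype_id", "cluster")
                   if c in df.columns]
    if sort_by and len(df):
        df = df.sort_values(list(sort_by), kind="mergesort")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep=_sep(path), na_rep="", index=False,
              float_format="%.15g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), na_values=_NA_TOKENS,
                       keep_default_na=False)
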