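"""Harmonization of per-study metadata and feature tables.

Pools heterogeneous cohort tables into one analysis-ready dataset:
standardizes metadata field names, drops sparsely-recorded variables,
keeps one sample per subject (left cheek preferred), removes organelle
(Mitochondria/Chloroplast) features, collapses amplicon variants to
species-level lineages, and merges per-study count tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_metadata",
    "deduplicate_subjects",
    "filter_features_by_taxonomy",
    "collapse_to_species",
    "merge_feature_tables",
    "DEFAULT_EXCLUDE_LABELS",
]

CANONICAL_COLUMNS = ["subject_id", "study_id", "cheek_side", "age", "gcfw", "tewl", "corneometer"]
REQUIRED_COLUMNS = ["subject_id", "study_id"]
NUMERIC_COLUMNS = ["age", "gcfw", "tewl", "corneometer"]
DEFAULT_EXCLUDE_LABELS = frozenset({"Mitochondria", "Chloroplast"})


def _coerce_numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "") \
        & (series.astype(str).str.upper() != "NA")
    if bad.any():
        logger.warning("column %r: %d unparseable value(s) set to missing", column, int(bad.sum()))
    return out


def standardize_metadata(
    raw_tables: list[pd.DataFrame],
    name_map: dict[str, str] | None = None,
    completeness_threshold: float = 0.40,
) -> pd.DataFrame:
    """Pool per-study metadata tables into canonical form.

    ``name_map`` maps study-specific column names (e.g. ``TEWL_right_face``)
    to canonical fields.  After pooling, any optional phenotype column whose
    non-missing fraction across all samples is <= ``completeness_threshold``
    is dropped (variables recorded for more than that fraction of samples
    are retained).  Each raw table must have a ``sample_id`` column or
    index; duplicated sample ids across studies are an error.
    """
    name_map = dict(name_map or {})
    frames = []
    for i, raw in enumerate(raw_tables):
        df = raw.copy()
        if df.index.name == "sample_id":
            df = df.reset_index()
        df = df.rename(columns=name_map)
        if "sample_id" in name_map.values() and "sample_id" not in df.columns:
            pass  # fallthrough to the error below
        if "sample_id" not in df.columns:
            raise ValueError(f"raw metadata table {i} has no sample_id column")
        frames.append(df)
    pooled = pd.concat(frames, axis=0, ignore_index=True)

    dup = pooled["sample_id"][pooled["sample_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate sample_id across studies: {sorted(map(str, dup))}")

    pooled = pooled.set_index("sample_id")
    for col in REQUIRED_COLUMNS:
        if col not in pooled.columns:
            raise ValueError(f"pooled metadata lacks required column {col!r}")

    out = pd.DataFrame(index=pooled.index)
    for col in CANONICAL_COLUMNS:
        if col not in pooled.columns:
            continue
        series = pooled[col]
        series = series.mask(series.astype(str).str.strip().isin({"", "NA", "nan", "NaN"}))
        if col in NUMERIC_COLUMNS:
            series = _coerce_numeric(series, col)
            frac = series.notna().mean()
            if frac <= completeness_threshold:
                logger.info(
                    "dropping %r: recorded for %.0f%% of samples (threshold %.0f%%)",
                    col, 100 * frac, 100 * completeness_threshold,
                )
                continue
        out[col] = series
    if "cheek_side" in out.columns:
        side = out["cheek_side"].astype(str).str.strip().str.lower()
        out["cheek_side"] = side.where(side.isin(["left", "right"]), "unknown")
    else:
        out["cheek_side"] = "unknown"
    return out[[c for c in CANONICAL_COLUMNS if c in out.columns]]


_SIDE_RANK = {"left": 0, "right": 1, "unknown": 2}


def deduplicate_subjects(metadata: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one sample per subject.

    Subjects sampled on both cheeks keep the left-cheek sample; otherwise
    the tie-break is the lexicographically smallest sample id."""
    df = metadata.copy()
    df["_side_rank"] = df["cheek_side"].map(_SIDE_RANK).fillna(2).astype(int)
    df["_sid"] = df.index.astype(str)
    df = df.sort_values(["_side_rank", "_sid"], kind="mergesort")
    kept = df[~df["subject_id"].duplicated(keep="first")]
    kept = kept.drop(columns=["_side_rank", "_sid"])
    return kept.loc[sorted(kept.index.astype(str))]


def filter_features_by_taxonomy(
    table: pd.DataFrame,
    taxonomy: pd.Series,
    exclude_labels=DEFAULT_EXCLUDE_LABELS,
) -> pd.DataFrame:
    """Drop features whose lineage contains any excluded label at any rank
    (case-insensitive).  Default labels remove organelle reads
    (Mitochondria, Chloroplast)."""
    labels = {str(s).lower() for s in exclude_labels}
    if not labels:
        raise ValueError("exclude_labels must be non-empty")
    missing = [f for f in table.columns if f not in taxonomy.index]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing}")
    lineages = taxonomy.loc[table.columns].astype(str).str.lower()
    drop = lineages.apply(lambda lin: any(lbl in lin for lbl in labels))
    return table.loc[:, ~drop.to_numpy()]


def collapse_to_species(table: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    """Sum features sharing an identical full lineage string into one
    species-level feature keyed by that lineage.

    Collapsing on the whole ranked lineage (not the species token alone)
    keeps homonymous species in different genera apart, and features with
    an empty species rank survive as their own truncated-lineage feature.
    Per-sample totals are conserved."""
    missing = [f for f in table.columns if f not in taxonomy.index]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing}")
    lineages = taxonomy.loc[table.columns].astype(str)
    collapsed = table.T.groupby(lineages.to_numpy()).sum().T
    collapsed = collapsed.loc[:, sorted(collapsed.columns)]
    collapsed.columns.name = "lineage"
    return collapsed


def merge_feature_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Union-merge samples x features count tables, zero-filling features
    absent from a study.  Sample ids must be globally unique."""
    if not tables:
        raise ValueError("no tables to merge")
    all_ids = pd.concat([pd.Series(t.index) for t in tables])
    dup = all_ids[all_ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate sample ids across tables: {sorted(map(str, dup))}")
    merged = pd.concat(tables, axis=0, join="outer").fillna(0)
    return merged.astype(np.int64)
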