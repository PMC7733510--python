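"""Readers and writers for the study's plain-text interchange formats.

Feature tables travel as TSV (wide matrix with identifier header/index,
or sparse ``sample<TAB>asv<TAB>count`` triplets), metadata and taxonomy
as TSV, trees as newick (parsed with scikit-bio).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import (
    RANKS,
    REQUIRED_METADATA_COLUMNS,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_feature_table_triplets",
    "write_feature_table_triplets",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "validate_tree",
]

ORIENTATIONS = ("samples_as_rows", "asvs_as_rows")


def read_feature_table(path, orientation: str = "samples_as_rows") -> FeatureTable:
    """Read a wide TSV count matrix.

    First column holds row identifiers, header holds column identifiers;
    ``orientation`` says whether rows are samples or ASVs. The returned
    table is always samples x ASVs.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            numeric[col] = df[col].astype(float)
        except ValueError as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric count in column {col!r}, row {bad!r}"
            ) from exc
    if orientation == "asvs_as_rows":
        numeric = numeric.T
    return FeatureTable(numeric)


def write_feature_table(table: FeatureTable, path, orientation: str = "samples_as_rows") -> None:
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    df = table.dataframe()
    if orientation == "asvs_as_rows":
        df = df.T
    df.to_csv(path, sep="\t")


def read_feature_table_triplets(path) -> FeatureTable:
    """Read a sparse triplet TSV: columns sample_id, asv_id, count.

    Unlisted (sample, ASV) cells are zero; duplicate triplets are an
    error rather than being summed silently.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:3]) != ["sample_id", "asv_id", "count"]:
        raise ValueError("triplet file must have columns sample_id, asv_id, count")
    dup = df.duplicated(subset=["sample_id", "asv_id"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["sample_id", "asv_id"]].tolist()
        raise ValueError(f"duplicate triplet for sample/ASV pair {pair}")
    wide = (
        df.pivot(index="sample_id", columns="asv_id", values="count")
        .fillna(0)
    )
    return FeatureTable(wide)


def write_feature_table_triplets(table: FeatureTable, path) -> None:
    df = table.dataframe().stack().rename("count").reset_index()
    df = df[df["count"] > 0]
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("metadata must contain a sample_id column")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.data
    out = df.copy()
    out["day_post_inoculation"] = out["day_post_inoculation"].astype(object).where(
        out["day_post_inoculation"].notna(), ""
    )
    out["subject_id"] = out["subject_id"].where(out["subject_id"].notna(), "")
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxonomy as either 7 rank columns or one ``lineage`` column.

    The single-column form is a semicolon-delimited SILVA-style string;
    rank prefixes like ``p__`` are stripped if present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "asv_id" not in df.columns:
        raise ValueError("taxonomy must contain an asv_id column")
    df = df.set_index("asv_id")
    if all(r in df.columns for r in RANKS):
        return TaxonomyTable(df)
    if "lineage" in df.columns:
        parsed = df["lineage"].map(_split_lineage)
        ranks_df = pd.DataFrame(parsed.tolist(), index=df.index, columns=list(RANKS))
        return TaxonomyTable(ranks_df)
    raise ValueError("taxonomy needs either the 7 rank columns or a lineage column")


def _split_lineage(lineage: str) -> list[str]:
    parts = [p.strip() for p in lineage.split(";")]
    cleaned = []
    for part in parts[: len(RANKS)]:
        if len(part) >= 3 and part[1:3] == "__":
            part = part[3:]
        cleaned.append(part)
    cleaned += [""] * (len(RANKS) - len(cleaned))
    return cleaned


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    taxonomy.data.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    validate_tree(tree)
    return tree


def validate_tree(tree: TreeNode) -> None:
    """Check tip labels are unique/present and branch lengths usable.

    Missing branch lengths are tolerated on the root only; negative or
    non-finite lengths are rejected.
    """
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise ValueError("tree has unlabeled tips")
    if len(names) != len(set(names)):
        raise ValueError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        bl = node.length
        if bl is None or not np.isfinite(bl) or bl < 0:
            raise ValueError(
                f"branch above {node.name or '<internal>'} has invalid length {bl!r}"
            )
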