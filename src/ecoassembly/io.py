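"""Readers and writers for the text formats the pipeline touches.

Count tables arrive as TSV/CSV (either orientation); trees as Newick
with branch lengths; metadata and environmental variables as CSV with
empty cells or "NA" for missing values.  All output is UTF-8 text.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal

import dendropy
import numpy as np
import pandas as pd

from .containers import CountTable, EnvironmentalMatrix, PairwiseResult, SampleMetadata

__all__ = [
    "read_count_table",
    "read_tree",
    "align_table_and_tree",
    "AlignmentReport",
    "write_pairwise_results",
    "read_pairwise_results",
    "read_environmental_matrix",
    "read_sample_metadata",
    "write_count_table",
]

Orientation = Literal["samples_as_rows", "taxa_as_rows"]

#: Tokens accepted as missing values in CSV environment/metadata tables.
NA_TOKENS = ("", "NA", "NaN", "nan")


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_count_table(
    path: str,
    orientation: Orientation = "samples_as_rows",
    drop_annotation_columns: bool = True,
) -> CountTable:
    """Load a delimited ASV count table and normalise to samples x taxa.

    Parameters
    ----------
    path : str
        TSV (default) or CSV file; first column holds row identifiers.
    orientation : {"samples_as_rows", "taxa_as_rows"}
        Declares what the file's rows are.  ``taxa_as_rows`` tables
        (the common ASV-table export) are transposed on load.
    drop_annotation_columns : bool
        ASV tables often carry non-numeric annotation columns
        (taxonomy strings, representative sequences).  When True these
        are silently dropped before validation; when False their
        presence is an error.

    Raises
    ------
    ValueError
        On duplicate identifiers, negative counts, or non-integer
        cells (the offending row/column is named).
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, header=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    non_numeric = [
        c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)
    ]
    if non_numeric:
        if not drop_annotation_columns:
            raise ValueError(f"non-numeric columns present: {non_numeric}")
        df = df.drop(columns=non_numeric)

    values = df.to_numpy()
    bad = np.argwhere(np.mod(values, 1) != 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-integer count {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )

    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountTable.from_dataframe(df.astype(np.int64))


def write_count_table(table: CountTable, path: str) -> None:
    """Write a count table as TSV (samples as rows)."""
    table.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_tree(path_or_string: str) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    Accepts a file path or a raw Newick string.  Quoted labels and
    zero-length branches are fine; duplicate tip labels are an error.
    """
    try:
        if os.path.exists(path_or_string):
            tree = dendropy.Tree.get(
                path=path_or_string, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                data=path_or_string, schema="newick", preserve_underscores=True
            )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    except Exception as exc:
        raise ValueError(f"could not parse Newick input: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    n_unlabelled = sum(1 for leaf in tree.leaf_node_iter() if leaf.taxon is None)
    if n_unlabelled:
        raise ValueError(f"{n_unlabelled} tree tips have no label")
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class AlignmentReport:
    """Which taxa were dropped from each side by align_table_and_tree."""

    dropped_from_table: list[str] = field(default_factory=list)
    dropped_from_tree: list[str] = field(default_factory=list)


def align_table_and_tree(
    table: CountTable,
    tree: dendropy.Tree,
    policy: Literal["strict", "intersect"] = "intersect",
) -> tuple[CountTable, dendropy.Tree, AlignmentReport]:
    """Reconcile the taxon sets of a count table and a phylogeny.

    ``strict`` errors unless the sets are identical; ``intersect``
    prunes both sides to the shared taxa (table column order preserved)
    and reports what was dropped.
    """
    table_taxa = set(table.taxon_ids)
    tree_taxa = set(tip_labels(tree))
    shared = table_taxa & tree_taxa
    report = AlignmentReport(
        dropped_from_table=sorted(table_taxa - shared),
        dropped_from_tree=sorted(tree_taxa - shared),
    )
    if policy == "strict":
        if table_taxa != tree_taxa:
            raise ValueError(
                "strict alignment: taxon sets differ "
                f"(table-only {len(table_taxa - tree_taxa)}, "
                f"tree-only {len(tree_taxa - table_taxa)})"
            )
        return table, tree, report
    if policy != "intersect":
        raise ValueError(f"unknown policy {policy!r}")
    if not shared:
        raise ValueError("table and tree share no taxa")
    if report.dropped_from_table or report.dropped_from_tree:
        table = table.select_taxa([t for t in table.taxon_ids if t in shared])
        if report.dropped_from_tree:
            tree = tree.clone(depth=1)
            keep = [tx for tx in tree.taxon_namespace if tx.label in shared]
            tree.retain_taxa(keep)
    return table, tree, report


_PAIRWISE_COLUMNS = [
    "sample_a",
    "sample_b",
    "bmntd",
    "bnti",
    "bray_curtis",
    "rc_bray",
    "process",
]


def write_pairwise_results(results: list[PairwiseResult], path: str) -> None:
    """Write one TSV row per unordered pair.

    ``rc_bray`` is left empty for pairs classified at the phylogenetic
    (deterministic) stage.
    """
    if not results:
        raise ValueError("no pairwise results to write")
    rows = [
        {
            "sample_a": r.sample_a,
            "sample_b": r.sample_b,
            "bmntd": r.bmntd,
            "bnti": r.bnti,
            "bray_curtis": r.bray_curtis,
            "rc_bray": "" if r.rc_bray is None else r.rc_bray,
            "process": r.process,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_PAIRWISE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_pairwise_results(path: str) -> list[PairwiseResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for rec in df.to_dict("records"):
        rc = rec["rc_bray"]
        out.append(
            PairwiseResult(
                sample_a=str(rec["sample_a"]),
                sample_b=str(rec["sample_b"]),
                bmntd=float(rec["bmntd"]),
                bnti=float(rec["bnti"]),
                bray_curtis=float(rec["bray_curtis"]),
                rc_bray=None if pd.isna(rc) else float(rc),
                process=str(rec["process"]),
            )
        )
    return out


def read_environmental_matrix(path: str, variables: list[str] | None = None) -> EnvironmentalMatrix:
    """Read a CSV of samples x environmental variables.

    Empty cells and "NA" are treated as missing.  Non-numeric columns
    are ignored unless explicitly requested via ``variables``.
    """
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, na_values=list(NA_TOKENS),
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    if variables is not None:
        df = df[variables]
    else:
        df = df.select_dtypes(include=[np.number])
    return EnvironmentalMatrix.from_dataframe(df.astype(float))


def read_sample_metadata(path: str) -> list[SampleMetadata]:
    """Read sample metadata CSV with sample_id, latitude, longitude, access_class."""
    df = pd.read_csv(path, sep=_sep_for(path), na_values=list(NA_TOKENS),
                     keep_default_na=False)
    required = {"sample_id", "latitude", "longitude", "access_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    out = []
    for rec in df.to_dict("records"):
        out.append(
            SampleMetadata(
                sample_id=str(rec["sample_id"]),
                latitude=float(rec["latitude"]),
                longitude=float(rec["longitude"]),
                access_class=str(rec["access_class"]),
                covariates={c: rec[c] for c in extra},
            )
        )
    return out
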