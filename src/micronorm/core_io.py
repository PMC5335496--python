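"""Data model and I/O for OTU count tables, phylogenies and group designs.

Count tables are integer matrices with taxa on rows and samples on columns,
the layout used throughout marker-gene surveys.  Library size (a sample's
column sum) is always recomputed from the matrix, never cached, because every
normalization method downstream keys off it.

Supported on-disk formats are plain TSV (first column taxon IDs, header row
sample IDs), the BIOM 1.0 JSON dialect, and Newick for rooted trees.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import skbio


class FormatError(ValueError):
    """Structural problem in an input file (duplicate IDs, bad dialect)."""


@dataclass
class CountTable:
    """Integer taxa x samples count matrix with IDs and optional group labels."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_group: Optional[dict[str, str]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = self.counts.astype(float)
            if np.any(~np.isfinite(as_float)):
                raise ValueError("counts contain NaN or infinite values")
            if np.any(as_float != np.round(as_float)):
                raise ValueError("counts must be integral")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums), recomputed on every call."""
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        group = None
        if self.sample_group is not None:
            group = {s: self.sample_group[s] for s in sample_ids if s in self.sample_group}
        return CountTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            sample_group=group,
            provenance=self.provenance,
        )


@dataclass
class PhyloTree:
    """Rooted tree with non-negative branch lengths, for UniFrac."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                warnings.warn("edge without a branch length; defaulting to 0")
                node.length = 0.0
            if node.length < 0:
                raise ValueError("negative branch length")

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))


@dataclass
class GroupDesign:
    """Sample-to-group mapping plus ordered numeric/categorical covariates.

    ``covariates`` is an ordered mapping term name -> per-sample values; for a
    sequential-SS PERMANOVA the insertion order is the model order (e.g. fit
    library size first, then the biological label).
    """

    groups: dict[str, str]
    covariates: Optional[pd.DataFrame] = None

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        return np.array([self.groups[s] for s in sample_ids])

    def two_group_masks(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
        """Boolean masks for the two groups; rejects designs with != 2 labels."""
        labels = self.labels_for(sample_ids)
        uniq = sorted(set(labels))
        if len(uniq) != 2:
            raise ValueError(f"two-group operation requires exactly 2 labels, got {uniq}")
        return labels == uniq[0], labels == uniq[1], (uniq[0], uniq[1])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a count table from TSV or BIOM-1.0 JSON.

    TSV dialect: first column holds taxon IDs, header row holds sample IDs.
    Non-integer or negative cells are rejected.
    """
    path = Path(path)
    if format == "tsv":
        # skip metadata lines ("# key=..."); the conventional "#OTU ID"
        # header (no space after the hash) is kept
        with open(path) as fh:
            skip = 0
            for line in fh:
                if line.startswith("# "):
                    skip += 1
                else:
                    break
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise FormatError("duplicate IDs in TSV")
        values = df.to_numpy()
        return CountTable(
            taxon_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            counts=values,
            provenance=str(path),
        )
    elif format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [str(r["id"]) for r in doc["rows"]]
        samples = [str(c["id"]) for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type", "sparse") == "sparse":
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        else:
            mat = np.asarray(doc["data"])
        group = None
        if any(c.get("metadata") and "group" in c["metadata"] for c in doc["columns"]):
            group = {
                str(c["id"]): c["metadata"]["group"]
                for c in doc["columns"]
                if c.get("metadata") and "group" in c["metadata"]
            }
        return CountTable(taxa, samples, mat, sample_group=group, provenance=str(path))
    raise ValueError(f"unknown format {format!r}")


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    """Write a count table; ``read_count_table(write(x)) == x`` for both formats."""
    path = Path(path)
    if format == "tsv":
        for tid in list(table.taxon_ids) + list(table.sample_ids):
            if "\t" in tid or "\n" in tid:
                raise ValueError(f"ID {tid!r} contains a TSV delimiter")
        table.to_dataframe().to_csv(path, sep="\t", index_label="#OTU ID")
    elif format == "biom":
        rows, cols = np.nonzero(table.counts)
        doc = {
            "id": table.provenance or None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "micronorm",
            "date": datetime.datetime.now().isoformat(),
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [
                {
                    "id": s,
                    "metadata": (
                        {"group": table.sample_group[s]}
                        if table.sample_group and s in table.sample_group
                        else None
                    ),
                }
                for s in table.sample_ids
            ],
            "data": [
                [int(r), int(c), int(table.counts[r, c])] for r, c in zip(rows, cols)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree; edges without lengths default to 0 (warned)."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# depth bookkeeping
# ---------------------------------------------------------------------------

def filter_low_depth(table: CountTable, percentile: float) -> tuple[CountTable, list[str]]:
    """Drop samples whose library size falls below the given quantile.

    The threshold is the linear-interpolation (type-7) quantile of the
    library-size distribution; samples strictly below it are dropped, samples
    exactly at the threshold are kept.  The dropped list is preserved so that
    clustering accuracy can optionally count them as misclassified.
    """
    if not 0 <= percentile <= 1:
        raise ValueError("percentile must be in [0, 1]")
    if table.n_samples == 0:
        raise ValueError("empty table")
    depths = table.library_sizes()
    threshold = np.quantile(depths, percentile)
    keep = depths >= threshold
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    return table.select_samples(kept_ids), dropped


def add_pseudocount(table: CountTable, c: float) -> np.ndarray:
    """Return counts + c as a float matrix; the table itself is untouched.

    c = 1 is the common log-transform guard; 0.01 is used ahead of edgeR-style
    log ratios; 0.001 is the ANCOM convention.
    """
    if c <= 0:
        raise ValueError("pseudocount must be positive")
    return table.counts.astype(float) + c
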