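"""Shared in-memory containers and identifier conventions.

Expression data lives on *genes*; the protein–protein interaction graph
lives on *proteins*.  Every cross-reference between the two identifier
spaces goes through an explicit :class:`IDMap` — mappings are never
inferred from identifier spelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rbpnet")

#: Closed vocabulary of RNA-binding-protein classes, keyed by the RNA
#: partner: mRNA, ribosome, pre-rRNA, tRNA, snRNA, snoRNA, non-coding RNA,
#: several partners ("diverse") or an unknown partner.  ``none`` marks
#: genes that are not RBPs.
RBP_CLASSES = (
    "mRBP",
    "rRBP",
    "rrRBP",
    "tRBP",
    "snRBP",
    "snoRBP",
    "ncRBP",
    "diverse",
    "unknown",
)
RBP_CLASS_VOCAB = RBP_CLASSES + ("none",)


class CountMatrix:
    """Integer gene × sample read-count matrix.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and sample
        identifiers as the columns.  Entries must be non-negative
        integers (raw read counts).
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if counts.shape[1] < 2:
            raise ValueError("a count matrix needs at least 2 samples")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            for g in counts.index:
                for s in counts.columns:
                    try:
                        float(counts.at[g, s])
                    except (TypeError, ValueError):
                        raise ValueError(
                            f"count for gene {g!r}, sample {s!r} is "
                            f"{counts.at[g, s]!r}; counts must be "
                            "non-negative integers"
                        ) from None
            values = counts.astype(float).to_numpy()
        if np.any(values < 0) or np.any(values != np.floor(values)):
            g, s = np.argwhere((values < 0) | (values != np.floor(values)))[0]
            raise ValueError(
                f"count for gene {counts.index[g]!r}, sample "
                f"{counts.columns[s]!r} is {values[g, s]!r}; "
                "counts must be non-negative integers"
            )
        self.counts = counts.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def validate_sample_table(samples: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check a sample table (columns ``sample``, ``group``) for consistency."""
    for col in ("sample", "group"):
        if col not in samples.columns:
            raise ValueError(f"sample table is missing column {col!r}")
    if samples["sample"].duplicated().any():
        dup = samples["sample"][samples["sample"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample identifier in sample table: {dup!r}")
    if counts is not None:
        missing = set(counts.samples) - set(samples["sample"])
        if missing:
            raise ValueError(f"samples missing from sample table: {sorted(missing)}")
    return samples.reset_index(drop=True)


def validate_annotation(anno: pd.DataFrame) -> pd.DataFrame:
    """Check a gene annotation table (``gene``, ``is_rbp``, ``rbp_class``).

    ``rbp_class`` is ``none`` exactly for non-RBP genes and the class
    vocabulary is closed.
    """
    for col in ("gene", "is_rbp", "rbp_class"):
        if col not in anno.columns:
            raise ValueError(f"annotation is missing column {col!r}")
    anno = anno.copy()
    if anno["is_rbp"].dtype != bool:
        anno["is_rbp"] = anno["is_rbp"].map(
            {True: True, False: False, "True": True, "False": False,
             "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
        )
        if anno["is_rbp"].isna().any():
            raise ValueError("is_rbp column must be boolean")
    bad = set(anno["rbp_class"]) - set(RBP_CLASS_VOCAB)
    if bad:
        raise ValueError(f"unknown rbp_class value(s): {sorted(bad)}")
    inconsistent = (anno["rbp_class"] == "none") != (~anno["is_rbp"])
    if inconsistent.any():
        g = anno.loc[inconsistent, "gene"].iloc[0]
        raise ValueError(f"gene {g!r}: rbp_class must be 'none' iff is_rbp is False")
    return anno.reset_index(drop=True)


@dataclass
class EdgeList:
    """Canonicalized undirected weighted edges in the STRING convention.

    Edges are stored with ``node_a <= node_b`` lexicographically, without
    self-edges, deduplicated keeping the maximum ``combined_score``
    (an edge passes a later confidence filter if any record passes).
    Scores live on STRING's integer 0–1000 confidence scale.
    """

    edges: pd.DataFrame  # columns node_a, node_b, combined_score
    n_self_edges_dropped: int = 0

    def __post_init__(self):
        e = self.edges
        for col in ("node_a", "node_b", "combined_score"):
            if col not in e.columns:
                raise ValueError(f"edge list missing column {col!r}")
        scores = e["combined_score"].to_numpy()
        if len(scores) and (scores.min() < 0 or scores.max() > 1000):
            bad = scores[(scores < 0) | (scores > 1000)][0]
            raise ValueError(f"combined_score {bad} outside [0, 1000]")
        if len(e) and (e["node_a"] > e["node_b"]).any():
            raise ValueError("edge list not canonicalized (node_a > node_b)")
        if len(e) and (e["node_a"] == e["node_b"]).any():
            raise ValueError("edge list contains self-edges")

    @classmethod
    def from_records(cls, records) -> "EdgeList":
        """Canonicalize raw (a, b, score) records: order endpoints, drop
        self-edges (logged), collapse duplicates keeping the max score."""
        n_self = 0
        best: dict[tuple[str, str], int] = {}
        for a, b, score in records:
            score = int(score)
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if score > best.get(key, -1):
                best[key] = score
        if n_self:
            logger.info("dropped %d self-edge(s) during canonicalization", n_self)
        rows = sorted(best.items())
        df = pd.DataFrame(
            [(a, b, s) for (a, b), s in rows],
            columns=["node_a", "node_b", "combined_score"],
        )
        return cls(df, n_self_edges_dropped=n_self)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class IDMap:
    """Many-to-many gene ↔ protein identifier mapping."""

    pairs: pd.DataFrame  # columns gene, protein; unique pairs

    def __post_init__(self):
        for col in ("gene", "protein"):
            if col not in self.pairs.columns:
                raise ValueError(f"id map missing column {col!r}")
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)
        self._gene_to_proteins = {
            g: set(sub["protein"]) for g, sub in self.pairs.groupby("gene")
        }
        self._protein_to_genes = {
            p: set(sub["gene"]) for p, sub in self.pairs.groupby("protein")
        }

    def proteins_for(self, gene: str) -> set[str]:
        """Proteins mapped to ``gene``; empty set if unmapped (not an error)."""
        return set(self._gene_to_proteins.get(gene, set()))

    def genes_for(self, protein: str) -> set[str]:
        return set(self._protein_to_genes.get(protein, set()))

    def mapping_summary(self) -> dict[str, int]:
        """Counts of genes with 0 (never stored), 1 and >1 proteins."""
        sizes = [len(v) for v in self._gene_to_proteins.values()]
        return {
            "genes_single_protein": sum(1 for s in sizes if s == 1),
            "genes_multi_protein": sum(1 for s in sizes if s > 1),
            "proteins": len(self._protein_to_genes),
        }

    def __len__(self) -> int:
        return len(self.pairs)
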