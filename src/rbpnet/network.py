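"""DE-constrained shortest-path analysis of a PPI and hub calling.

The procedure: filter a STRING-style PPI to confident edges (combined
score >= 500), annotate proteins with the differential-expression record
of their mapped genes, enumerate *all* unweighted shortest paths between
every pair of RBP proteins on the full filtered graph, keep only paths
in which every node (endpoints and intermediates alike) is significantly
differentially expressed, take the union of the retained paths as a new
network, and call "hub" genes as the nodes in the top degree percentile
of that union network.  Hubs are then broken down by RBP class and, for
a chosen contrast, split into low/high mean-expression groups by the
interquartile rule with a Wilcoxon rank-sum test per gene.

Paths are hop-count shortest paths: edge scores gate graph membership
but do not weight the search.  Significance filtering happens *after*
path enumeration on the full filtered graph, not on a pre-filtered
significant subgraph — the two differ, and the former is the analysis
order implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import networkx as nx
import numpy as np
import pandas as pd

from .containers import EdgeList, IDMap, validate_annotation, validate_sample_table
from .coexpression import wilcoxon_rank_sum

logger = logging.getLogger("rbpnet")


def build_graph(edges: EdgeList, min_score: int = 500) -> nx.Graph:
    """Confidence-filtered simple undirected PPI graph.

    Keeps edges with combined_score >= ``min_score``; nodes with no
    surviving edge are absent (the edge list carries no isolated nodes).
    """
    g = nx.Graph()
    kept = edges.edges[edges.edges["combined_score"] >= min_score]
    for a, b, s in kept.itertuples(index=False):
        g.add_edge(a, b, combined_score=int(s))
    if g.number_of_edges() == 0:
        raise ValueError(
            f"no edges with combined_score >= {min_score} "
            f"(input had {len(edges)} edges)"
        )
    logger.info(
        "PPI graph: %d nodes, %d edges (score >= %d; %d edges dropped)",
        g.number_of_nodes(),
        g.number_of_edges(),
        min_score,
        len(edges) - g.number_of_edges(),
    )
    return g


def annotate_graph(
    graph: nx.Graph,
    idmap: IDMap,
    de: pd.DataFrame,
    anno: pd.DataFrame | None = None,
) -> nx.Graph:
    """Stamp each protein node with its mapped gene's DE record and RBP flag.

    A gene mapping to several proteins stamps all of them.  When several
    genes map to one protein the record with the smaller adjusted p wins
    (conservative for path retention; the conflict is logged).  Proteins
    with no mapped gene or no DE record are marked non-significant
    (padj = NaN), so they can never survive path filtering.
    """
    de_of = de.set_index("gene")
    rbp_of: dict[str, bool] = {}
    if anno is not None:
        anno = validate_annotation(anno)
        rbp_of = dict(zip(anno["gene"], anno["is_rbp"]))
    class_of = (
        dict(zip(anno["gene"], anno["rbp_class"])) if anno is not None else {}
    )
    n_unmapped = n_no_de = n_stamped = n_conflicts = 0
    for node in graph.nodes:
        genes = sorted(idmap.genes_for(node))
        best = None
        for gene in genes:
            if gene not in de_of.index:
                continue
            rec = de_of.loc[gene]
            if best is None or rec["padj"] < best[1]["padj"]:
                if best is not None:
                    n_conflicts += 1
                    logger.info(
                        "protein %s: genes %s conflict; keeping smaller padj",
                        node,
                        genes,
                    )
                best = (gene, rec)
        attrs = {
            "gene": None,
            "log2fc": np.nan,
            "padj": np.nan,
            "is_rbp": False,
            "rbp_class": "none",
        }
        if not genes:
            n_unmapped += 1
        elif best is None:
            n_no_de += 1
            attrs["gene"] = genes[0]
            attrs["is_rbp"] = bool(rbp_of.get(genes[0], False))
            attrs["rbp_class"] = class_of.get(genes[0], "none")
        else:
            n_stamped += 1
            gene, rec = best
            attrs.update(
                gene=gene,
                log2fc=float(rec["log2fc"]),
                padj=float(rec["padj"]),
                is_rbp=bool(rbp_of.get(gene, False)),
                rbp_class=class_of.get(gene, "none"),
            )
        graph.nodes[node].update(attrs)
    logger.info(
        "annotation: %d stamped, %d without DE record, %d unmapped, %d conflicts",
        n_stamped,
        n_no_de,
        n_unmapped,
        n_conflicts,
    )
    return graph


@dataclass
class PathSet:
    """Shortest paths between RBP endpoint pairs."""

    paths: list[tuple[str, ...]]
    truncated_pairs: int = 0

    def __len__(self) -> int:
        return len(self.paths)


def _paths_from_predecessors(pred, source, target, cap):
    """Enumerate shortest paths target->source from a BFS predecessor DAG.

    Yields paths oriented source->target; stops after ``cap`` paths and
    reports whether more existed.
    """
    stack = [(target, (target,))]
    emitted = 0
    truncated = False
    while stack:
        node, suffix = stack.pop()
        if node == source:
            if cap is not None and emitted >= cap:
                truncated = True
                break
            yield suffix
            emitted += 1
            continue
        for p in sorted(pred.get(node, ()), reverse=True):
            stack.append((p, (p,) + suffix))
    if truncated:
        yield None  # sentinel consumed by the caller


def all_shortest_paths(
    graph: nx.Graph,
    endpoints,
    max_paths_per_pair: int | None = 100,
) -> PathSet:
    """All unweighted shortest paths between every unordered endpoint pair.

    Breadth-first, hop-count distances; edge scores are ignored once the
    graph is built.  Pairs in different components contribute nothing.
    Per pair, enumeration stops at ``max_paths_per_pair`` (None = no cap)
    and the number of truncated pairs is recorded.  Paths are emitted
    with the lexicographically smaller endpoint first and the final list
    is sorted, so output is canonical regardless of graph build order.
    """
    endpoints = sorted(set(endpoints) & set(graph.nodes))
    if len(endpoints) < 2:
        return PathSet([], 0)
    paths: list[tuple[str, ...]] = []
    truncated = 0
    for i, u in enumerate(endpoints):
        pred = nx.predecessor(graph, u)
        for v in endpoints[i + 1 :]:
            if v not in pred:
                continue  # different component
            pair_truncated = False
            for p in _paths_from_predecessors(pred, u, v, max_paths_per_pair):
                if p is None:
                    pair_truncated = True
                else:
                    paths.append(p)
            if pair_truncated:
                truncated += 1
    if truncated:
        logger.info("shortest paths truncated for %d pair(s)", truncated)
    paths.sort()
    return PathSet(paths, truncated)


def filter_paths(paths: PathSet, graph: nx.Graph, alpha: float = 0.05) -> PathSet:
    """Retain paths whose every node has adjusted p <= ``alpha``.

    The rule applies to endpoints and intermediates alike, RBP or not;
    unannotated nodes (padj NaN) never pass.
    """
    sig = {
        n
        for n, d in graph.nodes(data=True)
        if not np.isnan(d.get("padj", np.nan)) and d["padj"] <= alpha
    }
    kept = [p for p in paths.paths if all(n in sig for n in p)]
    return PathSet(kept, paths.truncated_pairs)


def union_network(paths: PathSet) -> nx.Graph:
    """Union of the retained paths: nodes, consecutive-pair edges, degrees."""
    g = nx.Graph()
    for p in paths.paths:
        g.add_nodes_from(p)
        g.add_edges_from(zip(p, p[1:]))
    if g.number_of_nodes() == 0:
        warnings.warn("no retained paths; the union network is empty", stacklevel=2)
    return g


def call_hubs(network: nx.Graph, percentile: float = 90.0) -> pd.DataFrame:
    """Degree-percentile hub calling on the union network.

    The threshold is the nearest-rank percentile of the degree multiset
    (the ceil(p/100 * n)-th smallest degree); every node with degree at
    or above it is a hub, so ties at the threshold are all included.
    Returns columns node, degree, is_hub sorted by decreasing degree.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot call hubs on an empty network")
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    degrees = dict(network.degree())
    sorted_deg = sorted(degrees.values())
    n = len(sorted_deg)
    rank = max(1, ceil(percentile / 100.0 * n))
    threshold = sorted_deg[rank - 1]
    df = pd.DataFrame(
        {"node": list(degrees), "degree": list(degrees.values())}
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    df["is_hub"] = df["degree"] >= threshold
    return df


def hub_composition(hubs: pd.DataFrame, graph: nx.Graph) -> pd.DataFrame:
    """RBP-class breakdown of hub nodes.

    Counts hub nodes per RBP class plus a non-RBP row, with each class's
    percentage among the RBP hubs.
    """
    hub_nodes = hubs.loc[hubs["is_hub"], "node"]
    classes = []
    for node in hub_nodes:
        d = graph.nodes[node]
        classes.append(d.get("rbp_class", "none") if d.get("is_rbp") else "non-RBP")
    counts = pd.Series(classes, dtype=object).value_counts().sort_index()
    n_rbp = int(sum(c for cls, c in counts.items() if cls != "non-RBP"))
    if n_rbp == 0:
        warnings.warn("no RBP hubs in the network", stacklevel=2)
    rows = [
        {
            "rbp_class": cls,
            "count": int(c),
            "pct_of_rbp_hubs": (100.0 * c / n_rbp) if cls != "non-RBP" and n_rbp else np.nan,
        }
        for cls, c in counts.items()
    ]
    return pd.DataFrame(rows)


def split_hubs_by_expression(
    hub_genes,
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Interquartile low/high split of hub genes with per-gene contrasts.

    Each hub gene's mean expression is taken across all samples of the
    two contrast groups.  Genes at or below the first quartile of those
    means are "low", at or above the third quartile "high" (quartiles by
    linear interpolation, boundaries inclusive), the rest "none".  Each
    low/high gene also gets a two-sided Wilcoxon rank-sum p-value
    comparing its expression between the two groups, flagged at p < 0.05.
    """
    samples = validate_sample_table(samples)
    cols = {
        g: [s for s in samples.loc[samples["group"] == g, "sample"] if s in expr.columns]
        for g in contrast
    }
    for g, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples in expr")
    hub_genes = [g for g in hub_genes if g in expr.index]
    all_cols = cols[contrast[0]] + cols[contrast[1]]
    means = expr.loc[hub_genes, all_cols].mean(axis=1)
    rows = []
    if len(means) and means.nunique() == 1:
        warnings.warn("all hub gene means equal; no low/high split", stacklevel=2)
        q1 = q3 = np.nan
    else:
        q1, q3 = np.percentile(means, [25, 75]) if len(means) else (np.nan, np.nan)
    for gene in hub_genes:
        m = float(means[gene])
        if np.isnan(q1):
            group = "none"
        elif m <= q1:
            group = "low"
        elif m >= q3:
            group = "high"
        else:
            group = "none"
        p = np.nan
        if group in ("low", "high"):
            p = wilcoxon_rank_sum(
                expr.loc[gene, cols[contrast[0]]], expr.loc[gene, cols[contrast[1]]]
            )
        rows.append(
            {
                "gene": gene,
                "mean_expression": m,
                "expression_group": group,
                "pvalue": p,
                "significant": bool(p < 0.05) if not np.isnan(p) else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results surface


class ShortestPathNetwork:
    """Model object for the DE-constrained shortest-path hub analysis.

    Parameters
    ----------
    edges
        STRING-dialect edge list (unfiltered; the confidence filter is
        applied here with ``min_score``).
    idmap
        Gene ↔ protein identifier map.
    de
        Differential-expression table for the contrast of interest.
    annotation
        Gene annotation marking RBP membership and class.
    min_score
        STRING combined-score threshold for graph membership.
    """

    def __init__(
        self,
        edges: EdgeList,
        idmap: IDMap,
        de: pd.DataFrame,
        annotation: pd.DataFrame,
        min_score: int = 500,
    ):
        self.graph = build_graph(edges, min_score)
        annotate_graph(self.graph, idmap, de, annotation)
        self.min_score = min_score
        self.idmap = idmap

    @property
    def rbp_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("is_rbp")
        )

    def fit(
        self,
        alpha: float = 0.05,
        percentile: float = 90.0,
        max_paths_per_pair: int | None = 100,
    ) -> "SPNetworkResults":
        paths = all_shortest_paths(self.graph, self.rbp_nodes, max_paths_per_pair)
        retained = filter_paths(paths, self.graph, alpha)
        net = union_network(retained)
        hubs = call_hubs(net, percentile) if net.number_of_nodes() else pd.DataFrame(
            columns=["node", "degree", "is_hub"]
        )
        return SPNetworkResults(
            model=self,
            alpha=alpha,
            percentile=percentile,
            paths=paths,
            retained=retained,
            network=net,
            hub_table=hubs,
        )


@dataclass
class SPNetworkResults:
    model: ShortestPathNetwork
    alpha: float
    percentile: float
    paths: PathSet
    retained: PathSet
    network: nx.Graph
    hub_table: pd.DataFrame

    @property
    def hubs(self) -> list[str]:
        return list(self.hub_table.loc[self.hub_table["is_hub"], "node"])

    def hub_genes(self) -> list[str]:
        return sorted(
            {
                self.model.graph.nodes[n].get("gene")
                for n in self.hubs
                if self.model.graph.nodes[n].get("gene")
            }
        )

    def composition(self) -> pd.DataFrame:
        return hub_composition(self.hub_table, self.model.graph)

    def split_by_expression(
        self, expr: pd.DataFrame, samples: pd.DataFrame, contrast: tuple[str, str]
    ) -> pd.DataFrame:
        return split_hubs_by_expression(self.hub_genes(), expr, samples, contrast)

    def summary(self) -> str:
        g = self.model.graph
        lines = [
            "Shortest-path PPI network analysis",
            "==================================",
            f"filtered PPI:      {g.number_of_nodes()} nodes, "
            f"{g.number_of_edges()} edges (score >= {self.model.min_score})",
            f"RBP endpoints:     {len(self.model.rbp_nodes)}",
            f"shortest paths:    {len(self.paths)} "
            f"({self.paths.truncated_pairs} pair(s) truncated)",
            f"significant paths: {len(self.retained)} (padj <= {self.alpha})",
            f"union network:     {self.network.number_of_nodes()} nodes, "
            f"{self.network.number_of_edges()} edges",
            f"hubs (top {100 - self.percentile:g}% degree): {len(self.hubs)}",
        ]
        if len(self.hub_table):
            lines.append("")
            lines.append("top nodes by degree:")
            lines.append(self.hub_table.head(10).to_string(index=False))
        return "\n".join(lines)
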