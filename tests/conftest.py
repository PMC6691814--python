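import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rbpnet.containers import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_counts(values, genes=None, samples=None) -> CountMatrix:
    values = np.asarray(values)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_sample_table(groups: dict[str, int]) -> pd.DataFrame:
    rows = []
    for label, n in groups.items():
        for r in range(1, n + 1):
            rows.append({"sample": f"{label}_{r}", "group": label, "replicate": r})
    return pd.DataFrame(rows)


@pytest.fixture
def five_node_graph():
    """The worked micro-example: A-B, B-C, A-D, D-C, C-E with per-node
    adjusted p-values such that only the route through D is fully
    significant at 0.05."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C"), ("C", "E")])
    padj = {"A": 0.01, "B": 0.2, "C": 0.01, "D": 0.03, "E": 0.02}
    for node, p in padj.items():
        g.nodes[node].update(padj=p, gene=node.lower(), is_rbp=node in ("A", "E"),
                             rbp_class="mRBP" if node in ("A", "E") else "none",
                             log2fc=1.0)
    return g
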