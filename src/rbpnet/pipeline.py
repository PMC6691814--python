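"""End-to-end pipeline orchestration on synthetic data.

Runs simulate → differential expression → co-expression → sample
structure → shortest-path network, persisting every intermediate table
and a plain-text report of the stage-by-stage counts.  All randomness
flows from the single configured seed through named per-stage
substreams, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .coexpression import CoexpressionAnalysis, sample_structure
from .dge import NBDifferentialExpression
from .network import ShortestPathNetwork
from .simulate import default_study_config, simulate_counts, simulate_ppi

logger = logging.getLogger("rbpnet")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Round-trips through YAML (`to_yaml` / `from_yaml`).
    """

    outdir: str = "rbpnet_run"
    seed: int = 0
    # stage parameters
    min_count: int = 10
    lfc_min: float = 1.5
    alpha: float = 0.05
    contrast: tuple[str, str] = ("HSC", "LSC")
    k_modules: int = 4
    min_score: int = 500
    percentile: float = 90.0
    max_paths_per_pair: int = 100
    fc_pseudocount: float = 0.5
    log_pseudocount: float = 1.0
    dispersion_moderation: float = 0.5

    def validate(self) -> "RunConfig":
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must be in (0, 100]")
        if self.min_count < 0 or self.min_score < 0 or self.lfc_min < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_paths_per_pair is not None and self.max_paths_per_pair < 1:
            raise ValueError("max_paths_per_pair must be >= 1 or null")
        return self

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["contrast"] = list(self.contrast)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "contrast" in d:
            d["contrast"] = tuple(d["contrast"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d).validate()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on freshly simulated data; return the stage counts.

    Writes all intermediate TSVs plus ``report.txt`` under
    ``config.outdir``.
    """
    config.validate()
    out = Path(config.outdir)
    os.makedirs(out, exist_ok=True)
    report: dict = {"seed": config.seed}

    # --- simulate -----------------------------------------------------
    sim = default_study_config(seed=config.seed)
    counts, samples, anno, truth = simulate_counts(sim)
    de_genes_true = sorted(truth.de_log2fc.get(config.contrast, {}))
    edges, idmap, truth = simulate_ppi(sim, de_genes_true, truth)
    io.write_counts(counts, out / "counts.tsv")
    io.write_table(samples, out / "samples.tsv", sort_by="sample")
    io.write_table(anno, out / "annotation.tsv", sort_by="gene")
    io.write_edge_list(edges, out / "edges.tsv")
    io.write_id_map(idmap, out / "idmap.tsv")
    report["simulated_genes"] = counts.shape[0]
    report["simulated_samples"] = counts.shape[1]
    report["simulated_edges"] = len(edges)

    # --- differential expression -------------------------------------
    model = NBDifferentialExpression(
        counts, samples, min_count=config.min_count, pseudocount=config.fc_pseudocount
    )
    report["genes_after_low_count_filter"] = model.counts.shape[0]
    de = model.fit(config.contrast, dispersion_moderation=config.dispersion_moderation)
    io.write_table(de.table, out / "de_table.tsv", sort_by="gene")
    selected = sorted(de.select(config.lfc_min, config.alpha))
    pd.Series(selected, name="gene").to_csv(
        out / "de_selected.tsv", sep="\t", index=False
    )
    report["de_selected"] = len(selected)

    # --- co-expression on RBP genes ----------------------------------
    expr = model.log_expression(config.log_pseudocount)
    rbp_genes = [
        g
        for g in anno.loc[anno["is_rbp"], "gene"]
        if g in expr.index
    ]
    coex = CoexpressionAnalysis(expr.loc[rbp_genes], samples, anno)
    coex_res = coex.fit(config.k_modules)
    io.write_table(coex_res.modules, out / "modules.tsv", sort_by="gene")
    io.write_table(
        coex_res.summarize().tests, out / "module_tests.tsv", sort_by="module"
    )
    io.write_table(
        coex_res.composition().reset_index(), out / "module_classes.tsv",
        sort_by="module",
    )
    report["rbp_genes_clustered"] = len(rbp_genes)
    report["module_sizes"] = {int(m): int(s) for m, s in coex_res.module_sizes.items()}

    # --- sample structure --------------------------------------------
    pca, sample_corr = sample_structure(expr.loc[rbp_genes])
    io.write_table(
        pca.scores.reset_index(names="sample").iloc[:, :4],
        out / "pca_scores.tsv",
        sort_by="sample",
    )
    io.write_table(
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pca.variance_ratio))],
                "variance_ratio": pca.variance_ratio,
            }
        ),
        out / "pca_variance.tsv",
        sort_by="component",
    )
    report["pca_top3_cumulative_variance"] = round(pca.cumulative_variance(3), 6)

    # --- shortest-path network ---------------------------------------
    spn = ShortestPathNetwork(edges, idmap, de.table, anno, config.min_score)
    res = spn.fit(
        alpha=config.alpha,
        percentile=config.percentile,
        max_paths_per_pair=config.max_paths_per_pair,
    )
    io.write_table(res.hub_table, out / "hub_table.tsv", sort_by="node")
    io.write_table(res.composition(), out / "hub_classes.tsv", sort_by="rbp_class")
    net_edges = pd.DataFrame(
        sorted(tuple(sorted(e)) for e in res.network.edges),
        columns=["node_a", "node_b"],
    )
    io.write_table(net_edges, out / "sp_network_edges.tsv", sort_by="node_a")
    split = res.split_by_expression(expr, samples, config.contrast)
    io.write_table(split, out / "hub_expression_split.tsv", sort_by="gene")
    report["ppi_nodes"] = spn.graph.number_of_nodes()
    report["ppi_edges"] = spn.graph.number_of_edges()
    report["paths_computed"] = len(res.paths)
    report["paths_truncated_pairs"] = res.paths.truncated_pairs
    report["paths_retained"] = len(res.retained)
    report["network_nodes"] = res.network.number_of_nodes()
    report["network_edges"] = res.network.number_of_edges()
    report["hubs"] = len(res.hubs)
    report["planted_hubs_recovered"] = len(
        truth.hub_proteins & set(res.hubs)
    )

    config.to_yaml(out / "config.yaml")
    with open(out / "report.txt", "w") as fh:
        fh.write("rbpnet pipeline report\n======================\n")
        for key, value in report.items():
            fh.write(f"{key}: {value}\n")
    logger.info("pipeline finished; outputs in %s", out)
    return report
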