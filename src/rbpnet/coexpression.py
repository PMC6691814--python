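"""Co-expression module detection and expression-profile structure.

Gene–gene Spearman correlation, hierarchical module extraction (the
heat-map "block" modules of the analysis), per-module cell-state
contrasts by Wilcoxon rank-sum, RBP-class composition, sample-level
structure (PCA and sample correlation) and UpSet-style exclusive set
intersections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .containers import validate_annotation, validate_sample_table
from .dge import _renumber_by_size

logger = logging.getLogger("rbpnet")


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation with p-values."""

    entities: list[str]
    rho: pd.DataFrame
    pval: pd.DataFrame
    constant_entities: tuple[str, ...] = ()

    def __post_init__(self):
        r = self.rho.to_numpy()
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")


def spearman_matrix(matrix: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman correlation between rows of ``matrix``.

    Average ranks for ties; p-values from the t approximation.  Rows
    with constant values get rho 0 (p 1) against everything and are
    flagged in ``constant_entities``.
    """
    if matrix.shape[1] < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    values = matrix.to_numpy(dtype=float)
    n_rows = values.shape[0]
    constant = np.array([np.all(v == v[0]) for v in values])
    # constant rows make spearmanr degenerate; correlate the rest and embed
    rho = np.zeros((n_rows, n_rows))
    pval = np.ones((n_rows, n_rows))
    live = np.flatnonzero(~constant)
    if len(live) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.spearmanr(values[live], axis=1)
        r = np.atleast_2d(res.statistic)
        p = np.atleast_2d(res.pvalue)
        if r.shape != (len(live), len(live)):  # spearmanr collapses 2 rows
            rv = float(np.ravel(r)[0])
            pv = float(np.ravel(p)[0])
            r = np.array([[1.0, rv], [rv, 1.0]])
            p = np.array([[0.0, pv], [pv, 0.0]])
        rho[np.ix_(live, live)] = np.nan_to_num(r, nan=0.0)
        pval[np.ix_(live, live)] = np.nan_to_num(p, nan=1.0)
    if constant.any():
        logger.warning(
            "%d constant row(s) assigned zero correlation", int(constant.sum())
        )
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    idx = matrix.index
    return CorrelationMatrix(
        entities=list(idx),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        pval=pd.DataFrame(pval, index=idx, columns=idx),
        constant_entities=tuple(idx[constant]),
    )


# the gene-wise entry point named for its role in the pipeline
gene_spearman = spearman_matrix


def detect_modules(corr: CorrelationMatrix, k: int) -> pd.DataFrame:
    """Cut the correlation dendrogram into ``k`` co-expression modules.

    Distance 1 - rho, average linkage.  Modules are numbered 1..k by
    decreasing size (ties by smallest gene identifier), mirroring the
    heat-map block modules selected in the underlying analysis.  Returns
    columns ``gene`` and ``module``.
    """
    n = len(corr.entities)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genes available")
    order = np.argsort(np.asarray(corr.entities))
    entities = [corr.entities[i] for i in order]
    dist = 1.0 - corr.rho.to_numpy()[np.ix_(order, order)]
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if n == 1:
        labels = np.array([1])
    else:
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    out = _renumber_by_size(pd.Index(entities), labels, colname="module")
    return out


def cut_height(corr: CorrelationMatrix, k: int) -> float:
    """Dendrogram height at which the average-linkage tree splits into k."""
    n = len(corr.entities)
    if n < 2 or k >= n:
        return 0.0
    dist = 1.0 - corr.rho.to_numpy()
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    heights = link[:, 2]
    return float(heights[-k]) if k > 1 else float(heights[-1])


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the pooled size is <= 20 and there are no
    ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class ModuleSummary:
    """Per-module, per-group medians and pairwise group contrasts."""

    medians: pd.DataFrame  # index module, columns group
    tests: pd.DataFrame  # module, group_a, group_b, pvalue


def summarize_module(
    assign: pd.DataFrame, expr: pd.DataFrame, samples: pd.DataFrame
) -> ModuleSummary:
    """Median expression and pairwise Wilcoxon contrasts per module.

    For each module and cell-state group the median is taken over every
    (gene, sample-in-group) expression value; every group pair is
    contrasted with a two-sided Wilcoxon rank-sum test on those pooled
    values.
    """
    samples = validate_sample_table(samples)
    group_samples = {
        g: [s for s in sub["sample"] if s in expr.columns]
        for g, sub in samples.groupby("group")
    }
    for g, cols in group_samples.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples in expr")
    groups = sorted(group_samples)
    med_rows, test_rows = [], []
    for module, sub in assign.groupby("module"):
        genes = [g for g in sub["gene"] if g in expr.index]
        pooled = {
            g: expr.loc[genes, group_samples[g]].to_numpy().ravel() for g in groups
        }
        med_rows.append(
            {"module": module, **{g: float(np.median(pooled[g])) for g in groups}}
        )
        for ga, gb in combinations(groups, 2):
            test_rows.append(
                {
                    "module": module,
                    "group_a": ga,
                    "group_b": gb,
                    "pvalue": wilcoxon_rank_sum(pooled[ga], pooled[gb]),
                }
            )
    medians = pd.DataFrame(med_rows).set_index("module")
    return ModuleSummary(medians=medians, tests=pd.DataFrame(test_rows))


def class_composition(assign: pd.DataFrame, anno: pd.DataFrame) -> pd.DataFrame:
    """Counts of RBP classes per module; row sums equal module sizes."""
    anno = validate_annotation(anno)
    class_of = dict(zip(anno["gene"], anno["rbp_class"]))
    missing = [g for g in assign["gene"] if g not in class_of]
    if missing:
        raise ValueError(f"gene {missing[0]!r} has no annotation")
    df = assign.assign(rbp_class=assign["gene"].map(class_of))
    table = (
        df.groupby(["module", "rbp_class"]).size().unstack(fill_value=0).sort_index()
    )
    table.columns.name = None
    return table


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray

    def cumulative_variance(self, n: int = 3) -> float:
        return float(self.variance_ratio[:n].sum())


def sample_structure(
    expr: pd.DataFrame,
) -> tuple[PCAResult, CorrelationMatrix]:
    """Sample-level structure of an expression matrix (genes × samples).

    PCA with samples as observations on gene-centered data (full
    decomposition, so variance ratios sum to 1), plus the Spearman
    correlation between samples with a hierarchical-clustering leaf
    order for heat-map display.
    """
    if expr.shape[1] < 3:
        raise ValueError("sample structure needs at least 3 samples")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    pca_res = PCAResult(
        scores=pd.DataFrame(
            scores,
            index=expr.columns,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        variance_ratio=pca.explained_variance_ratio_,
    )
    corr = spearman_matrix(expr.T)
    corr = _leaf_order(corr)
    return pca_res, corr


def _leaf_order(corr: CorrelationMatrix) -> CorrelationMatrix:
    """Reorder a correlation matrix by dendrogram leaves (deterministic)."""
    n = len(corr.entities)
    if n < 3:
        return corr
    dist = 1.0 - corr.rho.to_numpy()
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    entities = [corr.entities[i] for i in leaves]
    return CorrelationMatrix(
        entities=entities,
        rho=corr.rho.iloc[leaves, leaves],
        pval=corr.pval.iloc[leaves, leaves],
        constant_entities=corr.constant_entities,
    )


def set_intersections(named_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection-region sizes in UpSet semantics.

    Every non-empty membership bit-pattern over the input sets gets a
    row; ``size`` counts elements belonging to exactly that combination
    of sets.  Sizes sum to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(named_sets)
    rows = []
    universe: set = set().union(*named_sets.values())
    membership = {
        el: tuple(el in named_sets[n] for n in names) for el in universe
    }
    from collections import Counter

    counts = Counter(membership.values())
    for bits in range(1, 2 ** len(names)):
        pattern = tuple(bool(bits & (1 << i)) for i in range(len(names)))
        rows.append(
            {
                **{n: pattern[i] for i, n in enumerate(names)},
                "pattern": "".join("1" if b else "0" for b in pattern),
                "size": counts.get(pattern, 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results surface


class CoexpressionAnalysis:
    """Co-expression module model over an expression matrix.

    Parameters
    ----------
    expr
        Real-valued expression matrix, genes × samples (typically the
        shifted-log output of the DE model), already restricted to the
        genes of interest (e.g. RBP genes).
    samples
        Sample table assigning each sample a cell-state group.
    annotation
        Optional gene annotation for class-composition summaries.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        samples: pd.DataFrame,
        annotation: pd.DataFrame | None = None,
    ):
        self.expr = expr
        self.samples = validate_sample_table(samples)
        self.annotation = annotation
        self.corr = gene_spearman(expr)

    def fit(self, k: int = 4) -> "CoexpressionResults":
        modules = detect_modules(self.corr, k)
        return CoexpressionResults(self, k, modules)


@dataclass
class CoexpressionResults:
    model: CoexpressionAnalysis
    k: int
    modules: pd.DataFrame

    @property
    def module_sizes(self) -> pd.Series:
        return self.modules.groupby("module").size()

    def summarize(self) -> ModuleSummary:
        return summarize_module(self.modules, self.model.expr, self.model.samples)

    def composition(self) -> pd.DataFrame:
        if self.model.annotation is None:
            raise ValueError("no annotation attached to the model")
        return class_composition(self.modules, self.model.annotation)

    def cut_height(self) -> float:
        return cut_height(self.model.corr, self.k)

    def summary(self) -> str:
        sizes = self.module_sizes
        lines = [
            "Co-expression modules (Spearman, average linkage)",
            "=================================================",
            f"genes: {len(self.modules)}   modules: {self.k}   "
            f"cut height: {self.cut_height():.4f}",
            "module sizes: "
            + ", ".join(f"{m}: {s}" for m, s in sizes.items()),
        ]
        summ = self.summarize()
        lines.append("")
        lines.append("median expression per module and group:")
        lines.append(summ.medians.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)
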