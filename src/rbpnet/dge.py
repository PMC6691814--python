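"""Negative-binomial two-group differential expression.

The model is a simplified DESeq2-style analysis: low-count filtering,
median-of-ratios size factors, a shifted-log transform of normalized
counts, per-gene method-of-moments NB dispersion, and a Wald test on the
log2 ratio of normalized group means with Benjamini–Hochberg FDR
control.  Deliberate simplifications relative to DESeq2 (no rlog
shrinkage, no dispersion trend fitting, no independent filtering, no LFC
shrinkage, no outlier replacement) are documented in the methods note.

The surface follows the statsmodels convention: build a
:class:`NBDifferentialExpression` model from data, call :meth:`fit` for a
contrast, and work with the returned :class:`DEResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, validate_sample_table

logger = logging.getLogger("rbpnet")

ALPHA_FLOOR = 1e-8

DE_COLUMNS = ["gene", "base_mean", "log2fc", "se", "stat", "pvalue", "padj"]


# ---------------------------------------------------------------------------
# elementary operations


def filter_low_counts(counts: CountMatrix, min_count: int = 10) -> CountMatrix:
    """Remove genes whose count is below ``min_count`` in every sample."""
    keep = (counts.values() >= min_count).any(axis=1)
    if not keep.any():
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("low-count filter removed %d of %d genes", dropped, len(keep))
    return CountMatrix(counts.counts.loc[keep])


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each sample, the median over reference genes (genes with strictly
    positive counts in every sample) of count / per-gene geometric mean.
    """
    values = counts.values().astype(float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined (consider adding a pseudocount to the input)"
        )
    logc = np.log(values[positive])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def normalized_counts(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    return counts.counts / factors.reindex(counts.samples).to_numpy()[None, :]


def transform_log(
    counts: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Shifted log2 of normalized counts: log2(count/factor + pseudocount).

    A deliberate simplification of the regularized-log transform; it
    preserves the structure needed for PCA, correlation and clustering.
    """
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(normalized_counts(counts, factors) + pseudocount)


def _group_columns(counts: CountMatrix, samples: pd.DataFrame) -> dict[str, list[int]]:
    samples = validate_sample_table(samples, counts)
    pos = {s: i for i, s in enumerate(counts.samples)}
    cols: dict[str, list[int]] = {}
    for _, row in samples.iterrows():
        if row["sample"] in pos:
            cols.setdefault(row["group"], []).append(pos[row["sample"]])
    return cols


def estimate_dispersion(
    counts: CountMatrix,
    samples: pd.DataFrame,
    factors: pd.Series | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Within each group, alpha_g = (s^2 - m) / m^2; group estimates are
    pooled weighted by their degrees of freedom and floored at
    ``alpha_floor``.
    """
    if factors is None:
        factors = size_factors(counts)
    y = normalized_counts(counts, factors).to_numpy()
    groups = _group_columns(counts, samples)
    ests, weights = [], []
    for label, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 replicates")
        sub = y[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(np.maximum(m, 1e-300))
        ests.append(np.where(m > 0, a, 0.0))
        weights.append(len(cols) - 1)
    alpha = np.average(np.vstack(ests), axis=0, weights=weights)
    return pd.Series(
        np.maximum(alpha, alpha_floor), index=counts.genes, name="dispersion"
    )


def wald_test(
    counts: CountMatrix,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
    dispersion_moderation: float = 0.5,
) -> pd.DataFrame:
    """NB Wald test of ``test`` vs ``reference`` group means.

    log2fc = log2((m_test + c) / (m_ref + c)) on normalized group means
    with c = ``pseudocount``; the standard error comes from the delta
    method applied to the NB variance of the group means; p-values are
    two-sided normal and BH-adjusted.

    ``dispersion_moderation`` shrinks each gene's method-of-moments
    dispersion toward the across-gene mean (weight w on the mean).  With
    a handful of replicates the per-gene estimate is noisy enough to make
    the test anti-conservative; borrowing strength across genes restores
    null calibration.  Set to 0 for the unmoderated estimator.

    Returns a table with columns gene, base_mean, log2fc, se, stat,
    pvalue, padj.  Swapping the contrast direction negates log2fc and
    leaves p-values unchanged.
    """
    reference, test = contrast
    groups = _group_columns(counts, samples)
    for label in (reference, test):
        if label not in groups:
            raise ValueError(f"group {label!r} absent from sample table")
        if len(groups[label]) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
    if factors is None:
        factors = size_factors(counts)
    fvals = factors.reindex(counts.samples).to_numpy()
    y = (counts.values() / fvals[None, :]).astype(float)

    alpha = estimate_dispersion(counts, samples, factors).to_numpy()
    if dispersion_moderation > 0:
        alpha = (
            1.0 - dispersion_moderation
        ) * alpha + dispersion_moderation * alpha.mean()

    i_ref = np.array(groups[reference])
    i_test = np.array(groups[test])
    m_ref = y[:, i_ref].mean(axis=1)
    m_test = y[:, i_test].mean(axis=1)
    c = pseudocount
    log2fc = np.log2((m_test + c) / (m_ref + c))

    def var_of_mean(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        # Var(count/f) = (mu + alpha mu^2)/f^2 with mu = m*f per sample
        per_sample = m[:, None] / fvals[None, idx] + alpha[:, None] * m[:, None] ** 2
        return per_sample.sum(axis=1) / len(idx) ** 2

    v_ref = var_of_mean(m_ref, i_ref)
    v_test = var_of_mean(m_test, i_test)
    se = np.sqrt(v_test / (m_test + c) ** 2 + v_ref / (m_ref + c) ** 2) / np.log(2)
    se = np.maximum(se, 1e-12)
    z = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)

    both = np.concatenate([i_ref, i_test])
    return pd.DataFrame(
        {
            "gene": counts.genes,
            "base_mean": y[:, both].mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "stat": z,
            "pvalue": pvalue,
            "padj": padj,
        }
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def select_de(
    table: pd.DataFrame, lfc_min: float = 1.5, alpha: float = 0.05
) -> set[str]:
    """Genes with |log2fc| >= lfc_min and padj <= alpha (boundaries inclusive)."""
    mask = (table["log2fc"].abs() >= lfc_min) & (table["padj"] <= alpha)
    return set(table.loc[mask, "gene"])


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (sample sd); constant rows map to zero with a warning."""
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 values per row")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) z-scored to zero", stacklevel=2
        )
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


def cluster_rows(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Agglomerative clustering of rows into exactly ``k`` clusters.

    Euclidean distance, average linkage, tree cut with ``maxclust``;
    labels are renumbered by decreasing cluster size (ties broken by the
    lexicographically smallest row identifier).  Returns a table with
    columns ``gene`` and ``cluster`` (1..k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the {matrix.shape[0]} rows available")
    order = np.argsort(matrix.index.to_numpy())  # make join order canonical
    sorted_matrix = matrix.iloc[order]
    if matrix.shape[0] == 1:
        labels = np.array([1])
    else:
        link = hierarchy.linkage(sorted_matrix.to_numpy(), method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return _renumber_by_size(sorted_matrix.index, labels, colname="cluster")


def _renumber_by_size(index, labels, colname: str) -> pd.DataFrame:
    df = pd.DataFrame({"gene": index, colname: labels})
    key = df.groupby(colname)["gene"].agg(["size", "min"])
    ranked = key.sort_values(["size", "min"], ascending=[False, True])
    mapping = {old: new for new, old in enumerate(ranked.index, start=1)}
    df[colname] = df[colname].map(mapping)
    return df.sort_values("gene").reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results surface


class NBDifferentialExpression:
    """Two-group NB differential-expression model for a count matrix.

    Filtering and normalization happen at construction; :meth:`fit` runs
    the Wald test for one (reference, test) contrast.

    Examples
    --------
    >>> model = NBDifferentialExpression(counts, sample_table)
    >>> res = model.fit(("HSC", "LSC"))
    >>> res.select()                              # doctest: +SKIP
    """

    def __init__(
        self,
        counts: CountMatrix,
        samples: pd.DataFrame,
        min_count: int = 10,
        pseudocount: float = 0.5,
    ):
        self.samples = validate_sample_table(samples, counts)
        self.counts = filter_low_counts(counts, min_count)
        self.min_count = min_count
        self.pseudocount = pseudocount
        self.size_factors = size_factors(self.counts)

    @classmethod
    def from_files(cls, counts_path, samples_path, **kwargs):
        from . import io

        counts = io.read_counts(counts_path)
        samples = io.read_sample_table(samples_path, counts)
        return cls(counts, samples, **kwargs)

    def log_expression(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return transform_log(self.counts, self.size_factors, pseudocount)

    def fit(
        self, contrast: tuple[str, str], dispersion_moderation: float = 0.5
    ) -> "DEResults":
        table = wald_test(
            self.counts,
            self.samples,
            contrast,
            factors=self.size_factors,
            pseudocount=self.pseudocount,
            dispersion_moderation=dispersion_moderation,
        )
        return DEResults(self, contrast, table)


@dataclass
class DEResults:
    """Differential-expression results for one contrast."""

    model: NBDifferentialExpression
    contrast: tuple[str, str]
    table: pd.DataFrame

    def select(self, lfc_min: float = 1.5, alpha: float = 0.05) -> set[str]:
        return select_de(self.table, lfc_min, alpha)

    def cluster(self, k: int = 4, lfc_min: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
        """Cluster z-scored expression of the selected genes into ``k``
        expression-pattern clusters (renumbered by decreasing size)."""
        selected = sorted(self.select(lfc_min, alpha))
        if len(selected) < k:
            raise ValueError(
                f"only {len(selected)} selected genes; cannot form {k} clusters"
            )
        z = zscore_rows(self.model.log_expression().loc[selected])
        return cluster_rows(z, k)

    def summary(self, lfc_min: float = 1.5, alpha: float = 0.05) -> str:
        ref, test = self.contrast
        n = len(self.table)
        sel = self.select(lfc_min, alpha)
        up = sum(1 for g in sel if self.table.set_index("gene").loc[g, "log2fc"] > 0)
        lines = [
            "NB Wald differential expression",
            "===============================",
            f"contrast:         {test} vs {ref}",
            f"genes tested:     {n}",
            f"selected (|log2FC| >= {lfc_min}, padj <= {alpha}): {len(sel)}",
            f"  up in {test}:   {up}",
            f"  down in {test}: {len(sel) - up}",
            "",
            "top genes by adjusted p-value:",
        ]
        top = self.table.nsmallest(10, "padj")
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
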