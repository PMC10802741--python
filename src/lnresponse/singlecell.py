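"""Single-cell QC, normalization, module scoring and marker detection.

Cells are held in an AnnData (cells x genes raw counts).  QC removes cells
failing any of: mitochondrial or ribosomal count share above 25%, library
size or detected-feature count outside the 0.5--99.5 percentile band of all
cells, fewer than 200 detected features, or a Gini/Simpson diversity index
below 0.8 -- all statistics computed before any removal, so the kept set
does not depend on rule order.  Counts are then normalized to 1000 per cell
and log1p-transformed.

Gene-signature module scores follow the control-bin scheme: genes are
binned by mean expression, each signature gene draws control genes from its
own bin, and the per-cell score is the mean over signature genes minus the
mean over the pooled controls, so the expected score of a random gene set
is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse
import scipy.stats

from .clinical import wilcoxon_test

__all__ = [
    "QCThresholds", "ModuleScoreResult", "cell_qc_stats", "qc_filter",
    "diversity_indices", "normalize", "module_score", "cluster_markers",
    "summarize_cluster_scores",
]

MITO_PREFIXES = ("MT-",)
RIBO_PREFIXES = ("RPS", "RPL")


@dataclass
class QCThresholds:
    """QC cutoffs; set a field to None to disable that rule."""

    max_mito_fraction: Optional[float] = 0.25
    max_ribo_fraction: Optional[float] = 0.25
    percentile_band: Optional[Tuple[float, float]] = (0.5, 99.5)
    min_features: Optional[int] = 200
    min_gini: Optional[float] = 0.8
    min_simpson: Optional[float] = 0.8
    min_cells_per_gene: int = 5


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # per-cell signed score
    gene_set_id: str
    n_bins: int
    n_ctrl: int
    seed: int
    genes_used: List[str] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)


def _dense(X) -> np.ndarray:
    return X.toarray() if scipy.sparse.issparse(X) else np.asarray(X)


def diversity_indices(cell_counts: Sequence[float]) -> Tuple[float, float]:
    """Gini-based evenness and Gini-Simpson index of one cell's counts.

    Both are computed over detected (nonzero) genes so sparsity does not
    dominate: ``simpson = 1 - sum(p_i^2)`` and ``gini_diversity = 1 - G``
    with ``G`` the Gini coefficient of the detected-gene count vector.
    """
    x = np.asarray(cell_counts, float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero count vector")
    p = x / x.sum()
    simpson = 1.0 - float((p ** 2).sum())
    xs = np.sort(x)
    n = xs.size
    gini = (2.0 * np.sum(np.arange(1, n + 1) * xs) / (n * xs.sum())
            - (n + 1.0) / n)
    return float(1.0 - gini), simpson


def cell_qc_stats(adata: ad.AnnData,
                  mito_prefixes: Sequence[str] = MITO_PREFIXES,
                  ribo_prefixes: Sequence[str] = RIBO_PREFIXES) -> pd.DataFrame:
    """Per-cell QC statistics computed on the raw counts."""
    X = _dense(adata.X).astype(float)
    genes = adata.var_names.astype(str)
    is_mito = np.asarray(genes.str.startswith(tuple(mito_prefixes)))
    is_ribo = np.asarray(genes.str.startswith(tuple(ribo_prefixes)))
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts")
    stats = pd.DataFrame(index=adata.obs_names)
    stats["total_counts"] = totals
    stats["n_features"] = (X > 0).sum(axis=1)
    stats["mito_fraction"] = X[:, is_mito].sum(axis=1) / totals
    stats["ribo_fraction"] = X[:, is_ribo].sum(axis=1) / totals
    div = np.array([diversity_indices(row) for row in X])
    stats["gini_diversity"] = div[:, 0]
    stats["simpson_diversity"] = div[:, 1]
    stats.attrs["n_mito_genes"] = int(is_mito.sum())
    stats.attrs["n_ribo_genes"] = int(is_ribo.sum())
    return stats


def qc_filter(adata: ad.AnnData,
              thresholds: QCThresholds = QCThresholds(),
              mito_prefixes: Sequence[str] = MITO_PREFIXES,
              ribo_prefixes: Sequence[str] = RIBO_PREFIXES,
              ) -> Tuple[ad.AnnData, pd.DataFrame]:
    """Apply all QC rules; returns the filtered AnnData and a cell report.

    The report has one boolean column per rule (True = rule failed) plus
    ``kept``.  After cell removal, genes expressed in fewer than
    ``min_cells_per_gene`` kept cells and all mitochondrial/ribosomal genes
    are removed.
    """
    t = thresholds
    stats = cell_qc_stats(adata, mito_prefixes, ribo_prefixes)
    report = stats.copy()
    fail = pd.DataFrame(False, index=stats.index, columns=[])

    if t.max_mito_fraction is not None:
        if stats.attrs["n_mito_genes"] == 0:
            warnings.warn("no mitochondrial genes matched the configured "
                          "prefixes; mito rule skipped")
        else:
            fail["high_mito"] = stats["mito_fraction"] > t.max_mito_fraction
    if t.max_ribo_fraction is not None and stats.attrs["n_ribo_genes"] > 0:
        fail["high_ribo"] = stats["ribo_fraction"] > t.max_ribo_fraction
    if t.percentile_band is not None:
        lo, hi = t.percentile_band
        for col in ("n_features", "total_counts"):
            lo_v, hi_v = np.percentile(stats[col], [lo, hi])
            fail[f"{col}_outside_band"] = ((stats[col] < lo_v)
                                           | (stats[col] > hi_v))
    if t.min_features is not None:
        fail["few_features"] = stats["n_features"] < t.min_features
    if t.min_gini is not None:
        fail["low_gini"] = stats["gini_diversity"] < t.min_gini
    if t.min_simpson is not None:
        fail["low_simpson"] = stats["simpson_diversity"] < t.min_simpson

    kept = ~fail.any(axis=1) if len(fail.columns) else pd.Series(
        True, index=stats.index)
    report = report.join(fail)
    report["kept"] = kept

    filtered = adata[kept.to_numpy()].copy()
    X = _dense(filtered.X)
    genes = filtered.var_names.astype(str)
    drop = np.asarray(genes.str.startswith(tuple(mito_prefixes)))
    drop |= np.asarray(genes.str.startswith(tuple(ribo_prefixes)))
    drop |= (X > 0).sum(axis=0) < t.min_cells_per_gene
    filtered = filtered[:, ~drop].copy()
    return filtered, report


def normalize(adata: ad.AnnData, target_sum: float = 1000.0,
              scale: bool = False) -> ad.AnnData:
    """Scale each cell to ``target_sum`` counts, then log1p.

    With ``scale=True`` genes are additionally mean-centered and unit-
    scaled (for downstream embedding-style use; scores use unscaled data).
    """
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; run QC first")
    X = np.log1p(X / totals[:, None] * target_sum)
    if scale:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0,
                                            X.std(axis=0), 1.0)
    out = adata.copy()
    out.X = X
    out.uns["normalization"] = {"target_sum": target_sum, "log1p": True,
                                "scaled": bool(scale)}
    return out


def module_score(adata: ad.AnnData, gene_set: Iterable[str],
                 gene_set_id: str = "module", n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> ModuleScoreResult:
    """Control-binned per-cell expression score for a gene signature.

    Genes are ranked by mean expression across cells and split into
    ``n_bins`` equal-size bins; each signature gene contributes ``n_ctrl``
    control genes drawn from its bin (excluding signature genes; with
    replacement when the bin is thin).  Score(cell) = mean expression over
    signature genes minus mean over the pooled controls.
    """
    genes = adata.var_names
    present = [g for g in gene_set if g in set(genes)]
    if not present:
        raise ValueError("gene set entirely absent from the matrix")
    notes = []
    missing = len(list(gene_set)) - len(present)
    if missing:
        notes.append(f"{missing} signature genes absent")

    X = _dense(adata.X).astype(float)
    means = X.mean(axis=0)
    order = np.argsort(np.argsort(means, kind="stable"), kind="stable")
    bins = (order * n_bins) // len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    set_idx = np.array([gene_idx[g] for g in present])
    in_set = np.zeros(len(genes), bool)
    in_set[set_idx] = True

    rng = np.random.default_rng(seed)
    ctrl_idx: List[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:
            raise ValueError("no control genes available in an occupied bin")
        replace = pool.size < n_ctrl
        if replace:
            notes.append(f"bin {int(bins[gi])} thin "
                         f"({pool.size} genes); sampled with replacement")
        ctrl_idx.append(rng.choice(pool, n_ctrl, replace=replace))
    controls = np.concatenate(ctrl_idx)

    scores = X[:, set_idx].mean(axis=1) - X[:, controls].mean(axis=1)
    return ModuleScoreResult(
        scores=pd.Series(scores, index=adata.obs_names, name=gene_set_id),
        gene_set_id=gene_set_id, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed,
        genes_used=present, notes=notes)


def cluster_markers(adata: ad.AnnData, labels: Sequence,
                    top_n: int = 10) -> pd.DataFrame:
    """Cluster-vs-rest Wilcoxon marker table on normalized expression.

    Per gene and cluster: two-sided rank-sum p (exact for small tie-free
    groups), mean log-expression difference, Bonferroni adjustment across
    genes; the top ``top_n`` genes per cluster by adjusted p are returned.
    Singleton clusters are skipped with a warning.
    """
    labels = pd.Series(np.asarray(labels, dtype=object),
                       index=adata.obs_names)
    clusters = [c for c in pd.unique(labels)]
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    X = _dense(adata.X).astype(float)
    genes = np.asarray(adata.var_names)
    rows = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"singleton cluster {cl!r} skipped")
            continue
        A, B = X[mask], X[~mask]
        if max(A.shape[0], B.shape[0]) <= 25:
            pvals = np.array([wilcoxon_test(A[:, j], B[:, j])
                              for j in range(X.shape[1])])
        else:
            pvals = scipy.stats.mannwhitneyu(
                A, B, alternative="two-sided", method="asymptotic",
                axis=0).pvalue
        lfc = A.mean(axis=0) - B.mean(axis=0)
        p_bonf = np.minimum(1.0, pvals * X.shape[1])
        df = pd.DataFrame({"cluster": cl, "gene": genes, "logFC": lfc,
                           "p": pvals, "p_bonferroni": p_bonf})
        df = df.sort_values(["p_bonferroni", "p"],
                            kind="stable").head(top_n)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def summarize_cluster_scores(result: ModuleScoreResult, labels: Sequence,
                             major_type: Mapping | Sequence,
                             ) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-major-type maximum of per-subcluster mean scores.

    ``labels`` gives each cell's subcluster; ``major_type`` maps subcluster
    -> major cell population (or gives the major type per cell).  Returns
    the (major type, argmax subcluster, max mean score) table and the full
    per-subcluster mean series.  The maximum is taken as-is (negative means
    are not clipped).
    """
    labels = pd.Series(np.asarray(labels, dtype=object),
                       index=result.scores.index, name="subcluster")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("empty subcluster")
    sub_means = result.scores.groupby(labels).mean()
    if isinstance(major_type, Mapping):
        major_of_sub = pd.Series({s: major_type[s] for s in sub_means.index})
    else:
        per_cell = pd.Series(np.asarray(major_type, dtype=object),
                             index=labels.index)
        major_of_sub = per_cell.groupby(labels).first()
    out = []
    for major, subs in major_of_sub.groupby(major_of_sub):
        means = sub_means[subs.index]
        out.append({"major_type": major, "gene_set": result.gene_set_id,
                    "best_subcluster": means.idxmax(),
                    "max_score": float(means.max())})
    return pd.DataFrame(out), sub_means
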