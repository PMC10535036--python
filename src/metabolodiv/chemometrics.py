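"""Normalization, unsupervised structure discovery and factor ranking.

Intensities are quantile-normalized across samples (every sample column ends
up with the identical multiset of values, the mean order-statistic profile)
and then log2-transformed with a pseudocount.  PCA (centering only, no
unit-variance scaling) and Ward hierarchical clustering on 1 - Pearson
correlation distances look for sample structure; per-feature regression trees
rank the design factors (time, N concentration, genotype, organ) by their
aggregate contribution to intensity variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .feature_io import FeatureTable

__all__ = [
    "NormalizedMatrix",
    "PCAResult",
    "LinkageTree",
    "FactorImportance",
    "quantile_normalize",
    "normalize_quantile_log",
    "pca_2d",
    "hierarchical_cluster",
    "rank_factor_importance",
]

DESIGN_FACTORS = ("time_dag", "n_conc_mM", "genotype", "organ")


@dataclass
class NormalizedMatrix:
    """Features x samples matrix with transform provenance."""

    data: pd.DataFrame
    steps: list


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean order-statistic profile.

    Ties within a column receive the mean of the reference values at their
    tied positions (rank-average interpolation).  Idempotent on tie-free data.
    """
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 sample columns")
    vals = df.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    positions = np.arange(vals.shape[0], dtype=float)
    out = np.empty_like(vals)
    ranks = pd.DataFrame(vals).rank(method="average").to_numpy() - 1.0
    for j in range(vals.shape[1]):
        out[:, j] = np.interp(ranks[:, j], positions, ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_quantile_log(table: FeatureTable, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Quantile-normalize sample columns, then log2(x + pseudocount)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    qn = quantile_normalize(table.data)
    logged = np.log2(qn + pseudocount)
    return NormalizedMatrix(
        logged,
        steps=[("quantile", "mean order statistics"), ("log2", {"pseudocount": pseudocount})],
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # features x components
    var_explained: np.ndarray  # percent per component, non-increasing


def pca_2d(matrix: NormalizedMatrix, n_components: int = 2) -> PCAResult:
    """PCA of samples via SVD of the feature-centered matrix (no scaling)."""
    df = matrix.data if isinstance(matrix, NormalizedMatrix) else matrix
    x = df.to_numpy(dtype=float).T  # samples x features
    n_samples, n_features = x.shape
    max_comp = min(n_samples - 1, n_features)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(samples-1, features)={max_comp}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = (s**2).sum()
    var_pct = 100.0 * (s**2) / total if total > 0 else np.zeros_like(s)
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (u[:, :n_components] * s[:n_components]), index=df.columns, columns=comp_names
    )
    loadings = pd.DataFrame(vt[:n_components].T, index=df.index, columns=comp_names)
    return PCAResult(scores, loadings, var_pct[:n_components])


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class LinkageTree:
    """Ward merge sequence over samples on 1 - Pearson correlation distance."""

    linkage_matrix: np.ndarray
    sample_ids: list
    distance: str = "1 - pearson"
    method: str = "ward"

    def cut(self, n_clusters: int) -> dict:
        labels = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.sample_ids, labels.tolist()))


def correlation_distance(df: pd.DataFrame) -> np.ndarray:
    """Pairwise sample distance 1 - Pearson(sample_i, sample_j)."""
    stds = df.std(axis=0, ddof=0)
    flat = stds[stds == 0].index.tolist()
    if flat:
        raise ValidationError(f"constant sample column(s), correlation undefined: {flat}")
    corr = np.corrcoef(df.to_numpy(dtype=float).T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def hierarchical_cluster(matrix: NormalizedMatrix) -> LinkageTree:
    df = matrix.data if isinstance(matrix, NormalizedMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    d = correlation_distance(df)
    # Ward applied directly to correlation distances (Ward.D style), as
    # MetaboAnalyst-type heatmaps do; a known approximation since Ward is
    # derived for Euclidean distances.
    z = linkage(squareform(d, checks=False), method="ward")
    return LinkageTree(z, list(df.columns))


# ---------------------------------------------------------------------------
# decision-tree factor ranking
# ---------------------------------------------------------------------------

@dataclass
class FactorImportance:
    """Per-factor aggregate variance-reduction scores (percent) and ranks."""

    scores: dict   # factor -> percent of total importance
    ranks: dict    # factor -> 1..n (1 = most important)


def rank_factor_importance(
    table: FeatureTable,
    factors: tuple = DESIGN_FACTORS,
    max_depth: int = 3,
    seed: int = 0,
) -> FactorImportance:
    """Rank design factors by total impurity reduction over per-feature trees.

    For every feature a regression tree (depth <= max_depth) predicts its
    intensity from the encoded design factors; each factor's impurity
    reductions are summed across features (weighted by the feature's variance
    so flat features contribute nothing) and normalized to percentages.
    """
    from sklearn.tree import DecisionTreeRegressor

    meta = table.meta.loc[table.sample_ids]
    cols = []
    for f in factors:
        levels = pd.unique(meta[f])
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has a single level in the design")
        cols.append(pd.factorize(meta[f])[0])
    x = np.column_stack(cols).astype(float)
    y_all = table.data.to_numpy(dtype=float)
    totals = np.zeros(len(factors))
    for y in y_all:
        var = y.var()
        if var == 0:
            continue
        tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)
        tree.fit(x, y)
        totals += tree.feature_importances_ * var
    if totals.sum() == 0:
        pct = np.full(len(factors), 100.0 / len(factors))
    else:
        pct = 100.0 * totals / totals.sum()
    order = np.argsort(-pct, kind="stable")
    ranks = {factors[j]: int(r + 1) for r, j in enumerate(order)}
    return FactorImportance(
        scores={f: float(p) for f, p in zip(factors, pct)},
        ranks=ranks,
    )
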