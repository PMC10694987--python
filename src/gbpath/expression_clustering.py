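"""Signature-gene stratification of expression samples.

Samples (columns of a genes x samples matrix) are clustered on a signature
gene subset with k-means, k chosen by the silhouette method. Cluster
validity is assessed by a permutation test: each gene's values are scrambled
independently across samples (destroying covariance while preserving every
gene's marginal), the scrambled data is re-clustered at the same k, and the
between-minus-within mean pairwise distance is compared with the observed
value. The cluster-versus-diagnosis association on a 2x2 table uses the
Yates continuity-corrected chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.vq import kmeans2
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterAssignment",
    "PermutationTestResult",
    "subset_signature",
    "embed_samples",
    "kmeans_silhouette",
    "scramble_genes",
    "permutation_cluster_test",
    "chi2_2x2_yates",
]


@dataclass
class ClusterAssignment:
    """k-means sample assignment with the silhouette model-selection trail."""

    labels: pd.Series  # sample_id -> cluster in 1..k
    k: int
    silhouette_by_k: pd.DataFrame
    seed: int


@dataclass
class PermutationTestResult:
    """Observed cluster separation against the scrambled-data null.

    ``observed_separation = observed_between - observed_within`` (mean
    pairwise Euclidean distances); larger means tighter clustering, so the
    test is one-sided on exceedance. The empirical p uses the add-one rule
    and is therefore never zero.
    """

    observed_within: float
    observed_between: float
    observed_separation: float
    null_separations: np.ndarray
    empirical_p: float
    n_perm: int
    n_sampled_pairs: int
    seed: int
    flags: dict = field(default_factory=dict)


def subset_signature(expr: pd.DataFrame, genes) -> pd.DataFrame:
    """Row-subset an expression matrix to a signature gene list.

    Genes absent from the matrix are reported in a warning; fewer than two
    matches is an error (nothing to cluster on).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty signature gene list")
    present = [g for g in genes if g in expr.index]
    absent = [g for g in genes if g not in expr.index]
    if len(present) < 2:
        raise ValueError(
            f"only {len(present)} signature genes present in the matrix "
            f"(need >= 2); absent: {absent[:10]}"
        )
    if absent:
        warnings.warn(
            f"{len(absent)} signature genes absent from matrix: {absent}",
            stacklevel=2,
        )
    return expr.loc[present]


def embed_samples(
    expr: pd.DataFrame, perplexity: float = 10.0, seed: int = 0
) -> pd.DataFrame:
    """t-SNE 2-D embedding of samples (one point per column of ``expr``)."""
    n = expr.shape[1]
    if n <= 3 * perplexity:
        max_valid = (n - 1) / 3.0
        raise ValueError(
            f"t-SNE requires n_samples > 3*perplexity; with {n} samples the "
            f"largest valid perplexity is {max_valid:.1f}"
        )
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(expr.T.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=expr.columns, columns=["tsne_1", "tsne_2"])


def kmeans_silhouette(
    data: pd.DataFrame,
    k_range=range(2, 11),
    n_init: int = 10,
    seed: int = 0,
) -> ClusterAssignment:
    """k-means over a k grid; pick k maximizing mean silhouette width.

    ``data`` is genes x samples; samples are the points. For each k the best
    of ``n_init`` k-means restarts (by inertia) is scored by the mean
    Euclidean silhouette; ties in silhouette resolve to the smaller k.
    """
    X = data.T.to_numpy(dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ValueError(f"k_range must contain integers >= 2, got {ks}")
    if X.shape[0] < ks[-1] + 1:
        raise ValueError(
            f"need n_samples >= max(k_range)+1 = {ks[-1] + 1}, got {X.shape[0]}"
        )
    rows = []
    best = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        score = float(silhouette_score(X, km.labels_, metric="euclidean"))
        rows.append({"k": k, "silhouette": score, "inertia": float(km.inertia_)})
        if best is None or score > best[0]:
            best = (score, k, km.labels_)
    _, k_best, labels = best
    return ClusterAssignment(
        labels=pd.Series(labels + 1, index=data.columns, name="cluster"),
        k=k_best,
        silhouette_by_k=pd.DataFrame(rows).set_index("k"),
        seed=seed,
    )


def scramble_genes(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Scramble a samples x genes matrix: permute each gene independently.

    Preserves every gene's marginal multiset of values while destroying all
    gene-gene covariance — the null model of the permutation cluster test.
    """
    return rng.permuted(X, axis=0)


def _pair_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) index arrays of all unordered pairs, split same/different cluster."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    return np.stack([iu[same], ju[same]]), np.stack([iu[~same], ju[~same]])


def _mean_pair_distance(
    X: np.ndarray, pairs: np.ndarray, n_sampled: int, rng: np.random.Generator
) -> float:
    n_pairs = pairs.shape[1]
    if n_pairs == 0:
        return float("nan")
    if n_pairs > n_sampled:
        take = rng.choice(n_pairs, size=n_sampled, replace=False)
        pairs = pairs[:, take]
    diffs = X[pairs[0]] - X[pairs[1]]
    return float(np.sqrt((diffs**2).sum(axis=1)).mean())


def _separation(
    X: np.ndarray, labels: np.ndarray, n_sampled: int, rng: np.random.Generator
) -> tuple[float, float, float]:
    same, diff = _pair_indices(labels)
    within = _mean_pair_distance(X, same, n_sampled, rng)
    between = _mean_pair_distance(X, diff, n_sampled, rng)
    return within, between, between - within


def permutation_cluster_test(
    data: pd.DataFrame,
    assignment: ClusterAssignment,
    n_perm: int = 10_000,
    n_sampled_pairs: int = 10_000,
    seed: int = 0,
    reuse_labels: bool = False,
) -> PermutationTestResult:
    """Permutation validation of cluster separation.

    The null scrambles each gene independently across samples and, unless
    ``reuse_labels`` is set, re-clusters the scrambled matrix at the same k
    before recomputing the separation statistic. Pair distances are
    estimated from ``n_sampled_pairs`` uniformly sampled same-/different-
    cluster pairs (exhaustive when fewer pairs exist).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    labels_s = assignment.labels.reindex(data.columns)
    if labels_s.isna().any():
        raise ValueError("assignment does not cover all samples")
    labels = labels_s.to_numpy(dtype=int)
    k = assignment.k
    if k < 2:
        raise ValueError("need k >= 2 clusters")
    sizes = pd.Series(labels).value_counts()
    if sizes.min() < 2:
        raise ValueError(f"singleton cluster(s): {sizes[sizes < 2].index.tolist()}")
    X = data.T.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    within, between, observed = _separation(X, labels, n_sampled_pairs, rng)

    null = np.empty(n_perm)
    for b in range(n_perm):
        Xp = scramble_genes(X, rng)
        if reuse_labels:
            perm_labels = labels
        else:
            # Lightweight Lloyd k-means (k-means++ init) for the null refits.
            _, perm_labels = kmeans2(
                Xp, k, minit="++", seed=int(rng.integers(2**31 - 1))
            )
        null[b] = _separation(Xp, perm_labels, n_sampled_pairs, rng)[2]

    empirical_p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return PermutationTestResult(
        observed_within=within,
        observed_between=between,
        observed_separation=observed,
        null_separations=null,
        empirical_p=empirical_p,
        n_perm=n_perm,
        n_sampled_pairs=n_sampled_pairs,
        seed=seed,
    )


def chi2_2x2_yates(table) -> dict:
    """Yates continuity-corrected Pearson chi-square on a 2x2 table.

    ``chi2 = sum((max(|O - E| - 0.5, 0))**2 / E)`` with df = 1. Counts must
    be nonnegative integers with all margins positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any() or not np.allclose(obs, np.rint(obs)):
        raise ValueError("counts must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(row, col) / obs.sum()
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float((adj**2 / expected).sum())
    return {"chi2": chi2, "df": 1, "p": float(stats.chi2.sf(chi2, 1))}
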