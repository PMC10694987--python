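"""Morphology phenotyping of segmented cells.

Cells from two diagnostic groups (PD vs psPD) are balanced by subsampling
(8,000 per group by default), embedded in 2-D by UMAP on z-scored shape and
moment features (positions excluded), density-clustered with DBSCAN, and
clusters below a minimum size (160 cells by default) are relabeled as noise.
The retained clusters x groups contingency table is tested against an even
distribution with an uncorrected Pearson chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN

from gbpath.feature_extraction import MOMENT_FEATURES, SHAPE_FEATURES

__all__ = [
    "MorphoClusterResult",
    "DEFAULT_MORPHOLOGY_FEATURES",
    "balanced_subsample",
    "embed_morphology",
    "cluster_embedding",
    "cluster_group_chi2",
    "suggest_eps",
    "run_morphology_clustering",
]

# Shape + moment features, excluding absolute positions: where a cell sits in
# a tile must not define its morphology phenotype.
DEFAULT_MORPHOLOGY_FEATURES: list[str] = SHAPE_FEATURES + [
    f for f in MOMENT_FEATURES if f not in ("cx", "cy")
]


@dataclass
class MorphoClusterResult:
    stain: str
    embedding: np.ndarray
    labels: np.ndarray  # 1..m retained clusters, -1 noise
    contingency: pd.DataFrame
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    n_per_group: int
    seed: int
    omitted_clusters: list[int] = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def balanced_subsample(
    table: pd.DataFrame, group_col: str = "group", n_per_group: int = 8000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample exactly ``n_per_group`` rows per group, without replacement.

    Controls for uneven segmentation yield between groups before clustering.
    Deterministic given ``seed``; errors if any group is undersized.
    """
    counts = table[group_col].value_counts()
    small = counts[counts < n_per_group]
    if len(small):
        raise ValueError(
            f"groups too small for n_per_group={n_per_group}: "
            f"{small.to_dict()}"
        )
    rng = np.random.default_rng(seed)
    parts = []
    for group in sorted(counts.index):
        idx = table.index[table[group_col] == group].to_numpy()
        chosen = rng.choice(idx, size=n_per_group, replace=False)
        parts.append(table.loc[np.sort(chosen)])
    return pd.concat(parts)


def embed_morphology(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """UMAP 2-D embedding of z-scored morphology features.

    Constant feature columns cannot be z-scored and are dropped with a
    warning. Deterministic given ``seed`` (UMAP runs single-threaded under a
    fixed random state).
    """
    if feature_cols is None:
        feature_cols = [c for c in DEFAULT_MORPHOLOGY_FEATURES if c in table.columns]
    X = table[feature_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in morphology features")
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        dropped = [feature_cols[i] for i in np.nonzero(constant)[0]]
        warnings.warn(f"dropping constant feature columns: {dropped}", stacklevel=2)
        X = X[:, ~constant]
        sd = sd[~constant]
    X = (X - X.mean(axis=0)) / sd
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


def cluster_embedding(
    embedding: np.ndarray,
    eps: float,
    min_samples: int = 5,
    min_cluster_size: int = 160,
) -> tuple[np.ndarray, list[int]]:
    """DBSCAN the embedding; relabel undersized clusters as noise.

    Retained clusters are renumbered 1..m by decreasing size (ties broken by
    the original DBSCAN label). Returns ``(labels, omitted_cluster_sizes)``
    where omitted clusters are those DBSCAN found but that fell below
    ``min_cluster_size``.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        np.asarray(embedding, dtype=float)
    )
    labels = np.full(raw.shape, -1, dtype=int)
    values, counts = np.unique(raw[raw >= 0], return_counts=True)
    keep = counts >= min_cluster_size
    omitted = [int(c) for c in counts[~keep]]
    order = np.lexsort((values[keep], -counts[keep]))
    for new_label, old in enumerate(values[keep][order], start=1):
        labels[raw == old] = new_label
    return labels, omitted


def cluster_group_chi2(labels: np.ndarray, groups) -> dict:
    """Pearson chi-square of the retained-clusters x groups table.

    Noise points (label -1) are excluded. No continuity correction (general
    r x c contract); under a balanced design the expected counts embody the
    even-distribution baseline. Flags (rather than fails) tables with an
    expected cell below 1.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    mask = labels >= 0
    if mask.sum() == 0:
        raise ValueError("no retained clusters to test")
    contingency = pd.crosstab(
        pd.Series(labels[mask], name="cluster"),
        pd.Series(groups[mask], name="group"),
    )
    if contingency.shape[0] < 2 or contingency.shape[1] < 2:
        raise ValueError(
            f"need >= 2 clusters and >= 2 groups, got table shape "
            f"{contingency.shape}"
        )
    chi2, p, df, expected = stats.chi2_contingency(
        contingency.to_numpy(), correction=False
    )
    flags = {"low_expected": bool((expected < 1).any())}
    if flags["low_expected"]:
        warnings.warn("expected cell count below 1 in chi-square table", stacklevel=2)
    return {
        "contingency": contingency,
        "chi2_stat": float(chi2),
        "df": int(df),
        "p": float(p),
        "flags": flags,
    }


def suggest_eps(embedding: np.ndarray, min_samples: int = 5) -> float:
    """k-distance heuristic for a DBSCAN eps starting point.

    Returns the knee of the sorted min_samples-th neighbor distance curve
    (point of maximum deviation from the chord). A suggestion tool only —
    eps remains an explicit analysis parameter.
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(embedding, dtype=float)
    d, _ = cKDTree(pts).query(pts, k=min_samples + 1)
    curve = np.sort(d[:, min_samples])
    n = len(curve)
    t = np.linspace(0, 1, n)
    chord = curve[0] + t * (curve[-1] - curve[0])
    return float(curve[int(np.argmax(curve - chord))])


def run_morphology_clustering(
    table: pd.DataFrame,
    stain: str,
    eps: float,
    group_col: str = "group",
    n_per_group: int = 8000,
    min_samples: int = 5,
    min_cluster_size: int = 160,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> MorphoClusterResult:
    """Balanced subsample -> UMAP -> DBSCAN -> cluster-by-group chi-square."""
    sub = balanced_subsample(table, group_col, n_per_group, seed)
    embedding = embed_morphology(
        sub, n_neighbors=n_neighbors, min_dist=min_dist, seed=seed
    )
    labels, omitted = cluster_embedding(
        embedding, eps=eps, min_samples=min_samples,
        min_cluster_size=min_cluster_size,
    )
    test = cluster_group_chi2(labels, sub[group_col].to_numpy())
    return MorphoClusterResult(
        stain=stain,
        embedding=embedding,
        labels=labels,
        contingency=test["contingency"],
        chi2_stat=test["chi2_stat"],
        chi2_df=test["df"],
        chi2_p=test["p"],
        n_per_group=n_per_group,
        seed=seed,
        omitted_clusters=omitted,
        flags=test["flags"],
    )
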