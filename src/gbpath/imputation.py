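"""Cross-dataset gene imputation via housekeeping normalization and
random-forest regression.

Genes that fail QC in a target dataset (e.g. spatial profiling regions) are
estimated from a reference dataset (e.g. bulk RNA-seq) that shares gene
content. Both datasets are first put on a common within-sample scale by
dividing every gene by a shared low-variance housekeeping gene; predictor
genes for each target are selected by the Boruta shadow-feature procedure;
and a random-forest regressor trained on the reference predicts the target
gene in the target dataset. Every imputed value is flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

__all__ = [
    "HousekeepingSelection",
    "BorutaResult",
    "ImputationModel",
    "select_housekeeping",
    "normalize_by_housekeeping",
    "boruta_select",
    "train_imputer",
    "impute_gene",
]

logger = logging.getLogger(__name__)


@dataclass
class HousekeepingSelection:
    """Candidate housekeeping genes and the chosen normalizer.

    Candidates are genes present with all-nonzero expression in both
    datasets whose variance falls in the lower ``variance_percentile_cutoff``
    percentile in *both*; the chosen gene minimizes the sum of its variance
    ranks across the two datasets (ties to the lexicographically smallest
    gene id).
    """

    candidate_genes: list[str]
    chosen_gene: str
    variance_percentile_cutoff: float
    variances: pd.DataFrame  # candidates x {ref, target}


@dataclass
class BorutaResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    n_iterations: int
    hit_counts: pd.Series


@dataclass
class ImputationModel:
    target_gene: str
    confirmed_predictors: list[str]
    regressor: RandomForestRegressor
    housekeeping_gene: str
    metadata: dict = field(default_factory=dict)


def _nonzero_shared_genes(ref: pd.DataFrame, target: pd.DataFrame) -> list[str]:
    shared = ref.index.intersection(target.index)
    nz = [
        g
        for g in shared
        if (ref.loc[g] != 0).all() and (target.loc[g] != 0).all()
    ]
    return nz


def select_housekeeping(
    ref: pd.DataFrame, target: pd.DataFrame, pct: float = 0.20
) -> HousekeepingSelection:
    """Pick the shared low-variance housekeeping normalizer.

    Variance is computed on raw values over samples, within each dataset
    separately, over genes with non-zero expression everywhere in both.
    """
    if not 0.0 < pct <= 1.0:
        raise ValueError(f"pct must be in (0, 1], got {pct}")
    shared = _nonzero_shared_genes(ref, target)
    if len(shared) < 5:
        raise ValueError(
            f"only {len(shared)} shared all-nonzero genes (need >= 5)"
        )
    var_ref = ref.loc[shared].var(axis=1, ddof=1)
    var_tgt = target.loc[shared].var(axis=1, ddof=1)
    cut_ref = var_ref.quantile(pct)
    cut_tgt = var_tgt.quantile(pct)
    candidates = sorted(
        g for g in shared if var_ref[g] <= cut_ref and var_tgt[g] <= cut_tgt
    )
    if not candidates:
        raise ValueError(
            f"no gene falls in the lower {pct:.0%} variance percentile of "
            f"both datasets; try a larger pct"
        )
    rank_sum = var_ref.rank(method="min") + var_tgt.rank(method="min")
    # Ties on summed rank resolve lexicographically (candidates are sorted).
    chosen = min(candidates, key=lambda g: (rank_sum[g], g))
    return HousekeepingSelection(
        candidate_genes=candidates,
        chosen_gene=chosen,
        variance_percentile_cutoff=pct,
        variances=pd.DataFrame({"ref": var_ref, "target": var_tgt}).loc[candidates],
    )


def normalize_by_housekeeping(expr: pd.DataFrame, hk: str) -> pd.DataFrame:
    """Divide every gene by the housekeeping gene, within each sample.

    Puts two platforms on a common ratio scale; the housekeeping row becomes
    exactly 1, and the operation is idempotent. Errors if the housekeeping
    gene is zero (or absent) in any sample.
    """
    if hk not in expr.index:
        raise ValueError(f"housekeeping gene {hk!r} not in matrix")
    hk_values = expr.loc[hk]
    zero_samples = hk_values.index[hk_values == 0].tolist()
    if zero_samples:
        raise ValueError(
            f"housekeeping gene {hk!r} is zero in samples: {zero_samples}"
        )
    return expr.div(hk_values, axis=1)


def boruta_select(
    X: pd.DataFrame,
    y: pd.Series,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    n_estimators: int = 64,
    subsample: float = 0.8,
) -> BorutaResult:
    """Boruta all-relevant predictor selection for a regression target.

    ``X`` is predictors x samples. Each iteration appends a column-permuted
    shadow copy of every remaining predictor, fits a random-forest
    regressor, and scores a "hit" for every real predictor whose importance
    beats the maximum shadow importance. After each iteration, undecided
    predictors are tested against Binomial(n_iter, 1/2) with Bonferroni
    correction across them: significantly more hits than chance confirms,
    significantly fewer rejects. Predictors still undecided after
    ``max_iter`` are reported tentative. Shadow features can never be
    confirmed — they exist only as the importance bar.

    Each iteration refits on a fresh ``subsample`` fraction of the samples:
    impurity importances of a *fixed* noise column are otherwise stable
    across iterations (its spurious correlation never re-randomizes, unlike
    the freshly permuted shadows), which would let lucky noise columns
    accumulate hits; resampling makes spurious associations fluctuate while
    genuine signal persists.
    """
    if X.shape[0] < 2:
        raise ValueError("need >= 2 predictors")
    n_samples = X.shape[1]
    if n_samples < 10:
        raise ValueError(f"need >= 10 samples, got {n_samples}")
    y_arr = np.asarray(y, dtype=float)
    if y_arr.std() == 0:
        raise ValueError("constant target: nothing to select for")
    rng = np.random.default_rng(seed)
    predictors = list(X.index)
    undecided = set(predictors)
    confirmed: list[str] = []
    rejected: list[str] = []
    hits = pd.Series(0, index=predictors, dtype=int)
    Xs = X.T.to_numpy(dtype=float)  # samples x predictors
    col_of = {g: i for i, g in enumerate(predictors)}
    n_sub = max(10, int(round(subsample * n_samples)))

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        active = confirmed + sorted(undecided)
        cols = [col_of[g] for g in active]
        take = rng.choice(n_samples, size=min(n_sub, n_samples), replace=False)
        real = Xs[np.ix_(take, cols)]
        # At least 5 shadow columns: with too few, the max-shadow bar is a
        # max over a tiny sample and null features clear it too easily.
        shadow_blocks = [rng.permuted(real, axis=0)]
        while sum(b.shape[1] for b in shadow_blocks) < 5:
            shadow_blocks.append(rng.permuted(real, axis=0))
        design = np.hstack([real] + shadow_blocks)
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            max_features=max(1, design.shape[1] // 3),
        )
        forest.fit(design, y_arr[take])
        importances = forest.feature_importances_
        shadow_max = importances[len(active):].max()
        for g, imp in zip(active, importances[: len(active)]):
            if g in undecided and imp > shadow_max:
                hits[g] += 1
        # Decision step with Bonferroni across currently undecided predictors.
        if undecided:
            bonf_alpha = alpha / len(undecided)
            for g in sorted(undecided):
                h = int(hits[g])
                p_hi = stats.binom.sf(h - 1, n_iter, 0.5)  # P[X >= h]
                p_lo = stats.binom.cdf(h, n_iter, 0.5)  # P[X <= h]
                if p_hi < bonf_alpha:
                    confirmed.append(g)
                    undecided.discard(g)
                elif p_lo < bonf_alpha:
                    rejected.append(g)
                    undecided.discard(g)
        if not undecided:
            break
    return BorutaResult(
        confirmed=sorted(confirmed),
        rejected=sorted(rejected),
        tentative=sorted(undecided),
        n_iterations=n_iter,
        hit_counts=hits,
    )


def train_imputer(
    ref_norm: pd.DataFrame,
    target_gene: str,
    predictors: list[str],
    seed: int = 0,
    n_estimators: int = 200,
    holdout_fraction: float = 0.25,
    housekeeping_gene: str = "",
    low_quality_r: float = 0.3,
) -> ImputationModel:
    """Train the per-gene random-forest imputer on the reference dataset.

    A held-out split estimates the out-of-sample Pearson r, stored in the
    metadata (with ``low_quality=True`` below ``low_quality_r``); the final
    model is refit on all reference samples.
    """
    missing = [g for g in [target_gene, *predictors] if g not in ref_norm.index]
    if missing:
        raise ValueError(f"genes absent from reference: {missing}")
    n = ref_norm.shape[1]
    if n < 20:
        raise ValueError(f"need >= 20 training samples, got {n}")
    X = ref_norm.loc[predictors].T.to_numpy(dtype=float)
    y = ref_norm.loc[target_gene].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed
    )
    probe = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    probe.fit(X_tr, y_tr)
    pred = probe.predict(X_te)
    if np.std(pred) == 0 or np.std(y_te) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, y_te)[0, 1])
    model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    model.fit(X, y)
    if r < low_quality_r:
        logger.warning(
            "imputer for %s: held-out r=%.3f below %.2f, flagged low quality",
            target_gene, r, low_quality_r,
        )
    return ImputationModel(
        target_gene=target_gene,
        confirmed_predictors=list(predictors),
        regressor=model,
        housekeeping_gene=housekeeping_gene,
        metadata={
            "n_samples": int(n),
            "seed": seed,
            "holdout_r": r,
            "low_quality": bool(r < low_quality_r),
        },
    )


def impute_gene(model: ImputationModel, target_norm: pd.DataFrame) -> pd.DataFrame:
    """Predict the target gene for every sample of the normalized target set.

    Returns a table with the imputed value, an ``imputed=True`` flag, and
    the model's stored held-out quality metric, so downstream analyses can
    label imputed genes explicitly.
    """
    missing = [g for g in model.confirmed_predictors if g not in target_norm.index]
    if missing:
        raise ValueError(f"predictors absent from target matrix: {missing}")
    if target_norm.shape[1] == 0:
        return pd.DataFrame(
            columns=["value", "imputed", "holdout_r"], index=target_norm.columns
        )
    X = target_norm.loc[model.confirmed_predictors].T.to_numpy(dtype=float)
    values = model.regressor.predict(X)
    return pd.DataFrame(
        {
            "value": values,
            "imputed": True,
            "holdout_r": model.metadata.get("holdout_r", float("nan")),
        },
        index=target_norm.columns,
    )
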