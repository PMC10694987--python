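"""Supervised filtering of artifact segmentations.

Brightfield segmentation picks up punctate debris and faint non-specific
staining alongside true cells. Objects are classified positive/negative for
true signal by a random-forest classifier trained on labeled feature tables;
negatives and degenerate (sub-``min_area``) objects are removed before any
statistic is computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from gbpath.feature_extraction import (
    INTENSITY_FEATURES,
    MOMENT_FEATURES,
    SHAPE_FEATURES,
    TEXTURE_FEATURES,
)

__all__ = ["SignalClassifier", "train_signal_classifier", "filter_objects",
           "DEFAULT_CLASSIFIER_FEATURES"]

logger = logging.getLogger(__name__)

# Positions (cx, cy) are excluded: whether an object is real signal must not
# depend on where in the tile it sits.
DEFAULT_CLASSIFIER_FEATURES: list[str] = (
    SHAPE_FEATURES
    + [f for f in MOMENT_FEATURES if f not in ("cx", "cy")]
    + INTENSITY_FEATURES
    + TEXTURE_FEATURES
)


@dataclass
class SignalClassifier:
    """A trained positive/negative signal classifier with its provenance."""

    model: RandomForestClassifier
    features: list[str]
    metadata: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing}")
        return self.model.predict(table[self.features].to_numpy(dtype=float))

    def save(self, path) -> None:
        """Persist as JSON metadata + joblib model artifact side by side."""
        import joblib

        path = str(path)
        joblib.dump(self.model, path)
        with open(path + ".json", "w") as fh:
            json.dump({"features": self.features, "metadata": self.metadata}, fh)

    @classmethod
    def load(cls, path) -> "SignalClassifier":
        import joblib

        path = str(path)
        model = joblib.load(path)
        with open(path + ".json") as fh:
            meta = json.load(fh)
        return cls(model, meta["features"], meta["metadata"])


def train_signal_classifier(
    table: pd.DataFrame,
    label_col: str = "signal_label",
    features: list[str] | None = None,
    n_estimators: int = 200,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> SignalClassifier:
    """Train the positive/negative classifier on a labeled feature table.

    Labels must take exactly the values ``"positive"`` / ``"negative"`` with
    at least two examples of each. A stratified held-out split provides an
    out-of-sample accuracy estimate stored in the metadata; the final model
    is refit on all rows. Deterministic given ``seed``.
    """
    if features is None:
        features = [f for f in DEFAULT_CLASSIFIER_FEATURES if f in table.columns]
    labels = table[label_col].astype(str)
    counts = labels.value_counts()
    bad = set(counts.index) - {"positive", "negative"}
    if bad:
        raise ValueError(f"labels must be positive/negative, found {sorted(bad)}")
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(
            f"need >= 2 examples per class, got {counts.to_dict()}"
        )
    X = table[features].to_numpy(dtype=float)
    y = labels.to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=seed
    )
    probe = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    probe.fit(X_tr, y_tr)
    holdout_accuracy = float((probe.predict(X_te) == y_te).mean())

    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(X, y)
    return SignalClassifier(
        model,
        list(features),
        {
            "n_train": int(len(table)),
            "class_balance": {k: int(v) for k, v in counts.items()},
            "holdout_accuracy": holdout_accuracy,
            "seed": seed,
        },
    )


def filter_objects(
    table: pd.DataFrame, clf: SignalClassifier, min_area: float = 1.0
) -> pd.DataFrame:
    """Drop classifier-negative objects and objects below ``min_area`` px².

    Feature values are never mutated, so the operation is idempotent; removal
    counts are logged per image.
    """
    if table.empty:
        return table.copy()
    predictions = clf.predict(table)
    keep_signal = predictions == "positive"
    keep_area = table["area"].to_numpy(dtype=float) >= min_area
    keep = keep_signal & keep_area
    if "image_id" in table.columns:
        removed = table.loc[~keep]
        for image_id, sub in removed.groupby("image_id"):
            logger.info(
                "filter_objects: image %s removed %d objects", image_id, len(sub)
            )
    out = table.loc[keep].copy()
    out["signal_label"] = "positive"
    return out
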