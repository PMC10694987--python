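"""Per-cell shape, moment, intensity and texture features.

Each labeled object in a segmentation mask yields one row of features
computed from the mask geometry and the underlying stain channel. The
feature set mirrors what a pathology-informatics workflow feeds into
morphology clustering: size and boundary shape, second-moment ellipse
(orientation, eccentricity), intensity statistics, and four Haralick-style
gray-level co-occurrence (GLCM) scalars.

Conventions (pinned because the spatial statistics depend on them):

* coordinates are 0-based with ``cx`` = column and ``cy`` = row;
* perimeter counts inter-pixel boundary edges (4-neighbor crack length),
  image borders included;
* second central moments include the +1/12 per-pixel extent term (a pixel is
  a unit square, not a point), which keeps eccentricity strictly below 1
  for one-pixel-wide objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "shape_features",
    "moment_features",
    "intensity_features",
    "texture_features",
    "extract_features",
    "SHAPE_FEATURES",
    "MOMENT_FEATURES",
    "INTENSITY_FEATURES",
    "TEXTURE_FEATURES",
]

SHAPE_FEATURES = ["area", "perimeter", "radius_mean", "radius_sd", "radius_min", "radius_max"]
MOMENT_FEATURES = ["cx", "cy", "major_axis", "eccentricity", "theta"]
INTENSITY_FEATURES = ["intensity_mean", "intensity_sd", "intensity_q05", "intensity_q95"]
TEXTURE_FEATURES = ["glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity"]

# Per-pixel extent of a unit square, added to both diagonal second moments.
_PIXEL_VAR = 1.0 / 12.0


def _object_slices(labels: np.ndarray):
    from scipy import ndimage

    labels = np.asarray(labels)
    n = int(labels.max()) if labels.size else 0
    slices = ndimage.find_objects(labels, max_label=n) if n else []
    for obj_id, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        yield obj_id, sl, labels[sl] == obj_id


def shape_features(labels: np.ndarray) -> pd.DataFrame:
    """Area, crack-length perimeter and boundary-radius statistics per object."""
    rows = []
    for obj_id, sl, m in _object_slices(labels):
        rr, cc = np.nonzero(m)
        area = rr.size
        # Boundary edges: 4-neighbor exposure, padding so image borders count.
        padded = np.pad(m, 1)
        exposure = (
            (padded[1:-1, 1:-1] & ~padded[:-2, 1:-1]).sum()
            + (padded[1:-1, 1:-1] & ~padded[2:, 1:-1]).sum()
            + (padded[1:-1, 1:-1] & ~padded[1:-1, :-2]).sum()
            + (padded[1:-1, 1:-1] & ~padded[1:-1, 2:]).sum()
        )
        cy, cx = rr.mean(), cc.mean()
        # Boundary pixels: object pixels with at least one exposed 4-edge.
        interior = (
            padded[:-2, 1:-1]
            & padded[2:, 1:-1]
            & padded[1:-1, :-2]
            & padded[1:-1, 2:]
            & m
        )
        boundary = m & ~interior
        br, bc = np.nonzero(boundary)
        dists = np.hypot(br - cy, bc - cx)
        rows.append(
            {
                "object_id": obj_id,
                "area": float(area),
                "perimeter": float(exposure),
                "radius_mean": float(dists.mean()),
                "radius_sd": float(dists.std()),
                "radius_min": float(dists.min()),
                "radius_max": float(dists.max()),
            }
        )
    return pd.DataFrame(rows, columns=["object_id"] + SHAPE_FEATURES)


def moment_features(labels: np.ndarray) -> pd.DataFrame:
    """Centroid and second-central-moment ellipse per object.

    ``theta`` is the major-axis orientation in (-pi/2, pi/2], measured from
    the +x (column) axis toward +y taken upward (i.e. decreasing row index),
    matching the usual mathematical convention on images.
    """
    rows = []
    for obj_id, sl, m in _object_slices(labels):
        rr, cc = np.nonzero(m)
        r0, c0 = sl[0].start, sl[1].start
        cy, cx = rr.mean() + r0, cc.mean() + c0
        x = cc - cc.mean()
        y = -(rr - rr.mean())  # y axis upward
        mu20 = float((x * x).mean()) + _PIXEL_VAR
        mu02 = float((y * y).mean()) + _PIXEL_VAR
        mu11 = float((x * y).mean())
        common = np.hypot((mu20 - mu02) / 2.0, mu11)
        l1 = (mu20 + mu02) / 2.0 + common
        l2 = (mu20 + mu02) / 2.0 - common
        ecc = float(np.sqrt(max(0.0, 1.0 - l2 / l1))) if l1 > 0 else 0.0
        theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
        if theta <= -np.pi / 2:
            theta += np.pi
        rows.append(
            {
                "object_id": obj_id,
                "cx": float(cx),
                "cy": float(cy),
                "major_axis": float(4.0 * np.sqrt(max(l1, 0.0))),
                "eccentricity": ecc,
                "theta": float(theta),
            }
        )
    return pd.DataFrame(rows, columns=["object_id"] + MOMENT_FEATURES)


def intensity_features(labels: np.ndarray, channel: np.ndarray) -> pd.DataFrame:
    """Mean, sd and 5%/95% quantiles of channel values inside each object."""
    labels = np.asarray(labels)
    channel = np.asarray(channel, dtype=float)
    if labels.shape != channel.shape:
        raise ValueError(
            f"shape mismatch: labels {labels.shape} vs channel {channel.shape}"
        )
    rows = []
    for obj_id, sl, m in _object_slices(labels):
        vals = channel[sl][m]
        rows.append(
            {
                "object_id": obj_id,
                "intensity_mean": float(vals.mean()),
                "intensity_sd": float(vals.std()),
                "intensity_q05": float(np.quantile(vals, 0.05)),
                "intensity_q95": float(np.quantile(vals, 0.95)),
            }
        )
    return pd.DataFrame(rows, columns=["object_id"] + INTENSITY_FEATURES)


def _glcm_counts(q: np.ndarray, m: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts restricted to within-object pixel pairs."""
    dr, dc = offset
    h, w = q.shape
    a_rows = slice(max(0, -dr), min(h, h - dr))
    a_cols = slice(max(0, -dc), min(w, w - dc))
    b_rows = slice(max(0, dr), min(h, h + dr))
    b_cols = slice(max(0, dc), min(w, w + dc))
    valid = m[a_rows, a_cols] & m[b_rows, b_cols]
    i = q[a_rows, a_cols][valid]
    j = q[b_rows, b_cols][valid]
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    return counts + counts.T


def _glcm_props(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i = np.arange(levels)[:, None].astype(float)
    j = np.arange(levels)[None, :].astype(float)
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    sd_i = np.sqrt(float((p * (i - mu_i) ** 2).sum()))
    sd_j = np.sqrt(float((p * (j - mu_j) ** 2).sum()))
    if sd_i < 1e-15 or sd_j < 1e-15:
        correlation = 1.0  # constant texture is perfectly self-correlated
    else:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum() / (sd_i * sd_j))
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_energy": energy,
        "glcm_homogeneity": homogeneity,
    }


def texture_features(
    labels: np.ndarray,
    channel: np.ndarray,
    levels: int = 16,
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0)),
) -> pd.DataFrame:
    """GLCM contrast/correlation/energy/homogeneity per object.

    The channel (expected in [0, 1]) is quantized to ``levels`` gray levels;
    co-occurrence counts use only pixel pairs that both lie inside the
    object, are symmetrized and normalized, and the four scalars are
    averaged over offsets that produced at least one pair. Objects with no
    within-object pair at any offset get zero features and
    ``glcm_degenerate=True``.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    labels = np.asarray(labels)
    channel = np.asarray(channel, dtype=float)
    if labels.shape != channel.shape:
        raise ValueError(
            f"shape mismatch: labels {labels.shape} vs channel {channel.shape}"
        )
    q_full = np.clip((channel * levels).astype(int), 0, levels - 1)
    rows = []
    for obj_id, sl, m in _object_slices(labels):
        q = q_full[sl]
        per_offset = []
        for off in offsets:
            counts = _glcm_counts(q, m, off, levels)
            total = counts.sum()
            if total > 0:
                per_offset.append(_glcm_props(counts / total))
        if not per_offset:
            row = {k: 0.0 for k in TEXTURE_FEATURES}
            row["glcm_degenerate"] = True
        else:
            row = {
                k: float(np.mean([p[k] for p in per_offset]))
                for k in TEXTURE_FEATURES
            }
            row["glcm_degenerate"] = False
        row["object_id"] = obj_id
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["object_id"] + TEXTURE_FEATURES + ["glcm_degenerate"]
    )


def extract_features(
    labels: np.ndarray,
    channel: np.ndarray,
    image_id: str = "",
    group: str = "",
    region: str = "",
    levels: int = 16,
) -> pd.DataFrame:
    """Full per-cell feature table for one image.

    Joins shape, moment, intensity and texture features on ``object_id`` and
    attaches the image-level identity columns. ``signal_label`` starts as
    ``"unset"`` until the artifact filter classifies each object.
    """
    shape = shape_features(labels)
    if shape.empty:
        cols = (
            ["image_id", "object_id", "group", "region"]
            + SHAPE_FEATURES
            + MOMENT_FEATURES
            + INTENSITY_FEATURES
            + TEXTURE_FEATURES
            + ["glcm_degenerate", "signal_label"]
        )
        return pd.DataFrame(columns=cols)
    table = shape.merge(moment_features(labels), on="object_id")
    table = table.merge(intensity_features(labels, channel), on="object_id")
    table = table.merge(texture_features(labels, channel, levels=levels), on="object_id")
    table.insert(0, "image_id", image_id)
    table["group"] = group
    table["region"] = region
    table["signal_label"] = "unset"
    return table
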