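"""Object segmentation of stain channels.

Nuclei in a single-stain grayscale channel are separated from background by
Otsu's histogram threshold and grouped into objects by connected-component
labeling. Cells stained with a high-background membrane marker (CD163) are
instead segmented upstream by a CNN whose body/process probability maps are
thresholded and merged here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MergedLabelMask",
    "otsu_threshold",
    "binarize",
    "label_components",
    "threshold_probability_maps",
    "merge_masks",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on an ``n_bins`` histogram of the image.

    Returns the interior bin edge that maximizes the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` of the two classes it induces, breaking
    ties toward the lowest qualifying edge. Raises on a constant image
    (degenerate histogram: no threshold separates two classes).
    """
    img = np.asarray(img, dtype=float)
    if img.min() == img.max():
        raise ValueError("degenerate histogram: image is constant")
    counts, edges = np.histogram(img.ravel(), bins=n_bins)
    counts = counts.astype(float)
    total = counts.sum()
    # Cumulative statistics up to (and including) each bin.
    w0 = np.cumsum(counts)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mass = np.cumsum(counts * centers)
    total_mass = mass[-1]
    # Candidate thresholds are the interior edges: edge i splits bins
    # [0..i-1] from [i..n_bins-1].
    w0c = w0[:-1]
    w1c = total - w0c
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mass[:-1] / w0c
        mu1 = (total_mass - mass[:-1]) / w1c
        between = w0c * w1c * (mu0 - mu1) ** 2
    between = np.where((w0c == 0) | (w1c == 0), -np.inf, between)
    best = int(np.argmax(between))  # argmax takes the first (lowest) maximizer
    if not np.isfinite(between[best]):
        raise ValueError("degenerate histogram: all mass in one bin class")
    return float(edges[best + 1])


def binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground mask: pixel is 1 iff its value is strictly above ``threshold``."""
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    return (np.asarray(img) > threshold).astype(np.uint8)


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground components.

    Labels are assigned 1..n in raster-scan order of each component's first
    pixel; 0 is background. Connectivity is 4 (edge-adjacent) or 8
    (edge- or corner-adjacent).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask) != 0
    raw, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return raw.astype(np.int32)
    flat = raw.ravel()
    values, first_idx = np.unique(flat, return_index=True)
    fg = values > 0
    order = np.argsort(first_idx[fg], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[values[fg][order]] = np.arange(1, n + 1, dtype=np.int32)
    return remap[raw]


def threshold_probability_maps(
    body_map: np.ndarray, process_map: np.ndarray, global_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Binarize CNN body and process prediction maps at one global threshold."""
    if not 0.0 <= global_threshold <= 1.0:
        raise ValueError(
            f"global threshold must be in [0, 1], got {global_threshold}"
        )
    body_map = np.asarray(body_map, dtype=float)
    process_map = np.asarray(process_map, dtype=float)
    if body_map.shape != process_map.shape:
        raise ValueError(
            f"map shapes differ: {body_map.shape} vs {process_map.shape}"
        )
    return binarize(body_map, global_threshold), binarize(
        process_map, global_threshold
    )


@dataclass
class MergedLabelMask:
    """Whole-cell labels from merged body/process masks.

    ``contains_body[i]`` is True when object ``i + 1`` includes at least one
    body pixel (objects built purely from processes are flagged False).
    """

    labels: np.ndarray
    contains_body: np.ndarray

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def merge_masks(
    body: np.ndarray, process: np.ndarray, connectivity: int = 8
) -> MergedLabelMask:
    """Union body and process masks and label whole-cell objects."""
    body = np.asarray(body) != 0
    process = np.asarray(process) != 0
    if body.shape != process.shape:
        raise ValueError(f"mask shapes differ: {body.shape} vs {process.shape}")
    labels = label_components(body | process, connectivity=connectivity)
    n = int(labels.max())
    contains_body = np.zeros(n, dtype=bool)
    if n:
        hit = np.unique(labels[body])
        contains_body[hit[hit > 0] - 1] = True
    return MergedLabelMask(labels, contains_body)


def segment_channel(
    channel: np.ndarray, n_bins: int = 256, connectivity: int = 8
) -> tuple[np.ndarray, float]:
    """Otsu-threshold a stain channel and label the resulting objects.

    Convenience chain used by the pipeline; returns (label mask, threshold).
    A constant channel yields an empty mask with a warning instead of an
    error, since blank tiles are legitimate inputs at batch scale.
    """
    try:
        t = otsu_threshold(channel, n_bins=n_bins)
    except ValueError:
        warnings.warn("constant channel: returning empty segmentation", stacklevel=2)
        return np.zeros(np.asarray(channel).shape, dtype=np.int32), float("nan")
    return label_components(binarize(channel, t), connectivity=connectivity), t
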