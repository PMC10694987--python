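"""Color deconvolution of brightfield histology images.

Brightfield stains absorb light multiplicatively, so stain amounts mix
linearly in optical-density (OD) space (Beer–Lambert): ``OD = -log10(I/I0)``.
Given unit OD vectors for each stain, a pixel's OD vector is the stain
concentrations times the stain matrix, and concentrations are recovered by a
linear solve. This module converts RGB images to OD, unmixes them into
per-stain concentration channels (hematoxylin + eosin or hematoxylin + DAB),
and extracts rescaled single-stain grayscale channels for segmentation.

Default stain vectors are the published Ruifrok–Johnston values; they can be
overridden by any :class:`StainMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "StainMatrix",
    "ConcentrationImage",
    "HE_MATRIX",
    "HDAB_MATRIX",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "recompose",
    "stain_channel",
]


@dataclass(frozen=True)
class StainMatrix:
    """3x3 matrix of unit OD stain vectors (rows) over (R, G, B).

    The first two rows are the named stains; the third is a residual
    direction completing the basis. Rows must have unit Euclidean norm and
    the matrix must be invertible.
    """

    matrix: np.ndarray
    stain_names: tuple[str, str, str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain rows must be unit-norm; norms={norms}")
        if abs(np.linalg.det(m)) < 1e-12:
            bad = _nearly_parallel_rows(m, self.stain_names)
            raise ValueError(f"singular stain matrix; offending rows: {bad}")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "stain_names", tuple(self.stain_names))

    @classmethod
    def from_two_stains(
        cls,
        stain_1: np.ndarray,
        stain_2: np.ndarray,
        names: tuple[str, str],
    ) -> "StainMatrix":
        """Complete a 2-stain panel with a normalized cross-product residual."""
        v1 = _unit(np.asarray(stain_1, dtype=float))
        v2 = _unit(np.asarray(stain_2, dtype=float))
        v3 = np.cross(v1, v2)
        n3 = np.linalg.norm(v3)
        if n3 < 1e-12:
            raise ValueError(
                f"singular stain matrix; offending rows: {names[0]}, {names[1]} "
                "(parallel stain vectors)"
            )
        return cls(np.vstack([v1, v2, v3 / n3]), (names[0], names[1], "residual"))

    def to_yaml(self, path) -> None:
        data = {
            name: [float(x) for x in row]
            for name, row in zip(self.stain_names, self.matrix)
        }
        with open(path, "w") as fh:
            yaml.safe_dump({"stains": data, "order": list(self.stain_names)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "StainMatrix":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        order = data["order"]
        m = np.array([data["stains"][name] for name in order], dtype=float)
        return cls(m, tuple(order))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


def _nearly_parallel_rows(m: np.ndarray, names) -> str:
    for i in range(3):
        for j in range(i + 1, 3):
            if np.linalg.norm(np.cross(m[i], m[j])) < 1e-9:
                return f"{names[i]}, {names[j]}"
    return ", ".join(names)


# Ruifrok & Johnston OD vectors (R, G, B), unit-normalized on construction.
HE_MATRIX = StainMatrix.from_two_stains(
    [0.650, 0.704, 0.286], [0.072, 0.990, 0.105], ("hematoxylin", "eosin")
)
HDAB_MATRIX = StainMatrix.from_two_stains(
    [0.650, 0.704, 0.286], [0.268, 0.570, 0.776], ("hematoxylin", "dab")
)


@dataclass
class ConcentrationImage:
    """Per-stain concentration rasters with the unmixing bookkeeping.

    ``pixels`` is H x W x 3 (one channel per stain, clamped at 0);
    ``clamp_rate`` is the fraction of pixel-channel values that were negative
    before clamping.
    """

    pixels: np.ndarray
    stain_names: tuple[str, str, str]
    clamp_rate: float = 0.0
    scale_constants: dict = field(default_factory=dict)


def rgb_to_od(image: np.ndarray, i0: float = 255.0, eps: float = 1.0) -> np.ndarray:
    """Convert RGB intensities to optical density.

    ``OD = -log10((I + eps) / (i0 + eps))`` per channel. ``eps`` (default one
    intensity unit) guards against ``log(0)`` on saturated black pixels.
    """
    if i0 <= 0:
        raise ValueError(f"i0 must be positive, got {i0}")
    img = np.asarray(image, dtype=float)
    return -np.log10((img + eps) / (i0 + eps))


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Invert Beer–Lambert: ``I = i0 * 10**(-OD)`` (float result, not clipped)."""
    return i0 * np.power(10.0, -np.asarray(od, dtype=float))


def deconvolve(od: np.ndarray, stains: StainMatrix) -> ConcentrationImage:
    """Unmix an OD image into per-stain concentrations.

    Solves ``conc @ stains.matrix = od`` per pixel. Negative solutions
    (noise, stains outside the modeled panel) are clamped to zero; the clamp
    rate is recorded on the result rather than silently discarded.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected HxWx3 OD image, got shape {od.shape}")
    # conc = od @ inv(M); rows of M are stain vectors.
    inv = np.linalg.inv(stains.matrix)
    conc = od @ inv
    negative = conc < 0
    clamp_rate = float(negative.mean()) if conc.size else 0.0
    conc = np.where(negative, 0.0, conc)
    return ConcentrationImage(conc, stains.stain_names, clamp_rate)


def recompose(conc: ConcentrationImage, stains: StainMatrix) -> np.ndarray:
    """Remix concentrations back to OD (exact inverse when nothing clamped)."""
    return np.asarray(conc.pixels, dtype=float) @ stains.matrix


def stain_channel(conc: ConcentrationImage, stain_name: str) -> np.ndarray:
    """Extract one stain's concentrations as a [0, 1] grayscale channel.

    The channel is min-max scaled per image; the scaling constants are
    recorded in ``conc.scale_constants[stain_name]`` so the transform can be
    audited or undone. A constant channel cannot be rescaled and comes back
    as all zeros with a warning.
    """
    if stain_name not in conc.stain_names:
        raise ValueError(
            f"unknown stain {stain_name!r}; available: {conc.stain_names}"
        )
    idx = conc.stain_names.index(stain_name)
    channel = np.asarray(conc.pixels, dtype=float)[..., idx]
    lo, hi = float(channel.min()), float(channel.max())
    conc.scale_constants[stain_name] = {"min": lo, "max": hi}
    if hi - lo < 1e-300:
        warnings.warn(
            f"constant {stain_name} channel: min-max scaling degenerate, "
            "returning zeros",
            stacklevel=2,
        )
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)
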