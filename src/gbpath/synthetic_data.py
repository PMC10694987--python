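"""Ground-truthed synthetic IHC images and expression matrices.

Every downstream stage of the pipeline is validated against data with known
truth, generated here:

* **Images** — elliptical nuclei with uniform interior stain concentration,
  rendered under the Beer–Lambert model (concentration -> optical density via
  a stain matrix -> RGB by ``I = I0 * 10**(-OD)``). All nuclei carry
  hematoxylin; a configurable fraction additionally carries DAB. Optional
  low-intensity "artifact" objects mimic punctate debris for the artifact
  filter to learn against. The generator returns the rendered image, the true
  label mask, and a per-cell truth table with exact stain pixel counts.
* **Expression matrices** — log-normal genes x samples data with k latent
  sample clusters (signature genes shifted by a log-scale effect in their
  cluster), designed low-variance housekeeping genes, and target genes that
  are functions of named predictor genes with a prescribed R², for testing
  housekeeping normalization, Boruta selection and imputation.

Gene naming convention: signature genes ``sig_0001..``, housekeeping genes
``hk_001..``, all remaining genes ``gene_0001..``. Imputation target specs
refer to ``gene_*`` names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage.draw import ellipse as draw_ellipse

from gbpath.stain_deconvolution import HDAB_MATRIX, StainMatrix, od_to_rgb

__all__ = [
    "MorphologyPopulation",
    "ImageSimConfig",
    "ImageTruth",
    "IhcSimulation",
    "ImputationTargetSpec",
    "ExprSimConfig",
    "generate_ihc_image",
    "generate_expression",
    "save_rgb_image",
    "save_label_mask",
]

# Rejection-sampling cap for non-overlapping placement: gives a deterministic
# failure mode instead of an unbounded loop on over-dense configs.
MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class MorphologyPopulation:
    """One nucleus subpopulation: mixing fraction and size/shape distribution."""

    fraction: float
    mean_radius: float
    radius_sd: float
    eccentricity_mean: float
    eccentricity_sd: float = 0.05


@dataclass
class ImageSimConfig:
    """Parameters of one synthetic IHC tile.

    OD means are the uniform interior stain amounts of a nucleus, in optical
    density units (typical brightfield nuclei sit around 0.4–0.9 OD).
    ``artifact_fraction`` adds ``round(fraction * n_cells)`` decoy objects
    rendered at ``artifact_od_scale`` of the hematoxylin OD, excluded from
    the label mask but present in the truth table with ``is_artifact=True``.
    """

    width: int = 512
    height: int = 512
    n_cells: int = 200
    morphology_populations: list[MorphologyPopulation] = field(
        default_factory=lambda: [MorphologyPopulation(1.0, 8.0, 1.5, 0.5)]
    )
    dab_positive_fraction: float = 0.3
    hematoxylin_od_mean: float = 0.6
    dab_od_mean: float = 0.8
    background_noise_sd: float = 0.01
    allow_overlap: bool = True
    # Extra center-distance (px) required between objects when overlap is
    # disallowed: keeps rasterized ellipses from becoming 8-adjacent, so
    # "non-overlapping" also means "separable by connected components".
    placement_margin: float = 2.0
    artifact_fraction: float = 0.0
    artifact_od_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = sum(p.fraction for p in self.morphology_populations)
        if abs(fractions - 1.0) > 1e-9:
            raise ValueError(f"population fractions must sum to 1, got {fractions}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("hematoxylin_od_mean", "dab_od_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dab_positive_fraction <= 1.0:
            raise ValueError("dab_positive_fraction must be in [0, 1]")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must be in [0, 1]")

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if k != "morphology_populations"}
        data["morphology_populations"] = [
            dict(p.__dict__) for p in self.morphology_populations
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "ImageSimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        pops = [MorphologyPopulation(**p) for p in data.pop("morphology_populations")]
        return cls(morphology_populations=pops, **data)


@dataclass
class ImageTruth:
    """Ground truth for one generated tile.

    ``records`` has one row per drawn object (cells and artifacts); the pixel
    counts are exact recounts of the rendered concentration rasters
    (hematoxylin count includes artifact pixels, which are rendered in the
    hematoxylin raster).
    """

    records: pd.DataFrame
    true_dab_pixel_count: int
    true_hematoxylin_pixel_count: int


@dataclass
class IhcSimulation:
    """Everything :func:`generate_ihc_image` produces.

    ``hema_concentration`` / ``dab_concentration`` are the rendered per-pixel
    stain amounts (OD units) before conversion to RGB — the reference the
    deconvolution round-trip is checked against.
    """

    rgb: np.ndarray
    label_mask: np.ndarray
    truth: ImageTruth
    hema_concentration: np.ndarray
    dab_concentration: np.ndarray
    stain_matrix: StainMatrix
    config: ImageSimConfig


_TRUTH_COLUMNS = [
    "cell_id", "cx", "cy", "radius", "eccentricity", "theta",
    "population", "dab_positive", "is_artifact",
]


def _sample_cell(rng: np.random.Generator, pops, pop_probs):
    pop_idx = int(rng.choice(len(pops), p=pop_probs))
    pop = pops[pop_idx]
    radius = float(rng.normal(pop.mean_radius, pop.radius_sd))
    radius = max(radius, 1.5)
    ecc = float(np.clip(rng.normal(pop.eccentricity_mean, pop.eccentricity_sd), 0.0, 0.95))
    theta = float(rng.uniform(-np.pi / 2, np.pi / 2))
    return pop_idx, radius, ecc, theta


def generate_ihc_image(
    config: ImageSimConfig, stain_matrix: StainMatrix = HDAB_MATRIX
) -> IhcSimulation:
    """Render one synthetic brightfield tile with exact ground truth.

    Nuclei are ellipses (semi-major = drawn radius, semi-minor shrunk by the
    drawn eccentricity) with uniform interior concentration; DAB-positive
    nuclei carry both stains. With ``allow_overlap=False``, placement uses
    bounding-circle rejection sampling capped at
    :data:`MAX_PLACEMENT_ATTEMPTS` per object.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    pops = config.morphology_populations
    pop_probs = np.array([p.fraction for p in pops])
    pop_probs = pop_probs / pop_probs.sum()

    n_artifacts = int(round(config.artifact_fraction * config.n_cells))
    placed: list[dict] = []

    def place(is_artifact: bool, obj_index: int) -> dict:
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            pop_idx, radius, ecc, theta = _sample_cell(rng, pops, pop_probs)
            if is_artifact:
                radius = max(radius * 0.5, 1.5)  # artifacts skew small/punctate
            a = radius
            if a >= min(h, w) / 2 - 1:
                raise ValueError(
                    f"ellipse semi-axis {a:.1f}px does not fit a {h}x{w} image"
                )
            cy = float(rng.uniform(a, h - 1 - a))
            cx = float(rng.uniform(a, w - 1 - a))
            if config.allow_overlap or all(
                np.hypot(cx - q["cx"], cy - q["cy"])
                > a + q["radius"] + config.placement_margin
                for q in placed
            ):
                return {
                    "cx": cx, "cy": cy, "radius": radius, "eccentricity": ecc,
                    "theta": theta, "population": pop_idx,
                    "is_artifact": is_artifact,
                }
        density = config.n_cells * np.pi * np.mean(
            [p.mean_radius for p in pops]
        ) ** 2 / (h * w)
        raise RuntimeError(
            f"could not place object {obj_index} without overlap after "
            f"{MAX_PLACEMENT_ATTEMPTS} attempts (approximate areal density "
            f"{density:.2f}); reduce n_cells or allow overlap"
        )

    for i in range(config.n_cells):
        placed.append(place(False, i))
    for i in range(n_artifacts):
        placed.append(place(True, config.n_cells + i))

    hema = np.zeros((h, w), dtype=float)
    dab = np.zeros((h, w), dtype=float)
    label_mask = np.zeros((h, w), dtype=np.int32)
    records = []
    cell_id = 0
    for obj in placed:
        a = obj["radius"]
        b = a * np.sqrt(1.0 - obj["eccentricity"] ** 2)
        rr, cc = draw_ellipse(
            obj["cy"], obj["cx"], b, a, shape=(h, w), rotation=obj["theta"]
        )
        if rr.size == 0:
            raise ValueError(
                f"zero-area ellipse (semi-axes {a:.2f} x {b:.2f}px)"
            )
        if obj["is_artifact"]:
            dab_positive = False
            np.maximum.at(hema, (rr, cc), config.artifact_od_scale * config.hematoxylin_od_mean)
        else:
            cell_id += 1
            dab_positive = bool(rng.random() < config.dab_positive_fraction)
            np.maximum.at(hema, (rr, cc), config.hematoxylin_od_mean)
            if dab_positive:
                np.maximum.at(dab, (rr, cc), config.dab_od_mean)
            label_mask[rr, cc] = cell_id
        records.append(
            {
                "cell_id": cell_id if not obj["is_artifact"] else -len(records) - 1,
                "cx": obj["cx"], "cy": obj["cy"], "radius": obj["radius"],
                "eccentricity": obj["eccentricity"], "theta": obj["theta"],
                "population": obj["population"],
                "dab_positive": dab_positive,
                "is_artifact": obj["is_artifact"],
            }
        )

    records_df = pd.DataFrame(records, columns=_TRUTH_COLUMNS)
    truth = ImageTruth(
        records=records_df,
        true_dab_pixel_count=int((dab > 0).sum()),
        true_hematoxylin_pixel_count=int((hema > 0).sum()),
    )

    # Beer–Lambert rendering: concentrations -> OD -> transmitted intensity.
    conc = np.stack([hema, dab, np.zeros_like(hema)], axis=-1)
    od = conc @ stain_matrix.matrix
    if config.background_noise_sd > 0:
        od = od + rng.normal(0.0, config.background_noise_sd, size=od.shape)
        od = np.maximum(od, 0.0)
    rgb = np.clip(np.rint(od_to_rgb(od)), 0, 255).astype(np.uint8)
    return IhcSimulation(rgb, label_mask, truth, hema, dab, stain_matrix, config)


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass(frozen=True)
class ImputationTargetSpec:
    """A target gene functionally dependent on named predictor genes.

    ``true_r2`` is the population fraction of log-scale target variance
    explained by the functional form (the rest is independent noise).
    """

    target: str
    predictors: tuple[str, ...]
    form: str = "linear"
    true_r2: float = 0.9

    def __post_init__(self) -> None:
        if self.form not in ("linear", "interaction"):
            raise ValueError(f"form must be linear|interaction, got {self.form!r}")
        if not 0.0 < self.true_r2 < 1.0:
            raise ValueError(f"true_r2 must be in (0, 1), got {self.true_r2}")
        if self.target in self.predictors:
            raise ValueError("target gene cannot be its own predictor")
        object.__setattr__(self, "predictors", tuple(self.predictors))


@dataclass
class ExprSimConfig:
    """Parameters of one synthetic expression matrix.

    Defaults mirror the bulk clustering setting the pipeline targets: around
    a hundred samples, a signature of 83 genes carrying cluster effects among
    a larger panel, and a handful of designed housekeeping genes whose
    coefficient of variation sits well below the biological noise.
    Values are log-normal: normal in log space (effects and noise are
    log-scale shifts), exponentiated, hence strictly positive.
    """

    n_samples: int = 109
    n_genes: int = 500
    k_clusters: int = 3
    signature_size: int = 83
    effect_size: float = 1.0
    noise_sd: float = 0.5
    n_housekeeping: int = 10
    housekeeping_cv: float = 0.02
    imputation_targets: list[ImputationTargetSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.k_clusters > self.n_samples:
            raise ValueError(
                f"k_clusters={self.k_clusters} exceeds n_samples={self.n_samples}"
            )
        reserved = self.signature_size + self.n_housekeeping + len(self.imputation_targets)
        if reserved > self.n_genes:
            raise ValueError(
                f"signature ({self.signature_size}) + housekeeping "
                f"({self.n_housekeeping}) + targets ({len(self.imputation_targets)}) "
                f"exceed n_genes={self.n_genes}"
            )


def _gene_names(config: ExprSimConfig) -> tuple[list[str], list[str], list[str]]:
    sig = [f"sig_{i:04d}" for i in range(1, config.signature_size + 1)]
    hk = [f"hk_{i:03d}" for i in range(1, config.n_housekeeping + 1)]
    n_other = config.n_genes - len(sig) - len(hk)
    other = [f"gene_{i:04d}" for i in range(1, n_other + 1)]
    return sig, hk, other


def generate_expression(
    config: ExprSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate a genes x samples matrix with known structure.

    Returns ``(expr, labels, annotations)``: the positive expression matrix,
    the true cluster label (1..k) per sample, and a per-gene annotation table
    (role, assigned cluster for signature genes, imputation role).
    """
    rng = np.random.default_rng(config.seed)
    sig, hk, other = _gene_names(config)
    genes = sig + hk + other
    samples = [f"s_{i:03d}" for i in range(1, config.n_samples + 1)]

    target_names = {t.target for t in config.imputation_targets}
    predictor_names = set()
    for t in config.imputation_targets:
        missing = [g for g in (t.target, *t.predictors) if g not in other]
        if missing:
            raise ValueError(
                f"imputation spec refers to non-'gene_*' names: {missing}"
            )
        predictor_names.update(t.predictors)
    if target_names & predictor_names:
        raise ValueError("a target gene cannot also serve as a predictor")

    # Balanced latent clusters, shuffled.
    labels = np.array(
        [(i % config.k_clusters) + 1 for i in range(config.n_samples)]
    )
    rng.shuffle(labels)

    base = rng.normal(2.0, 0.3, size=len(genes))
    log_expr = np.empty((len(genes), config.n_samples))
    annotations = []
    gene_index = {g: i for i, g in enumerate(genes)}

    for i, g in enumerate(sig):
        cluster = (i % config.k_clusters) + 1
        row = base[gene_index[g]] + rng.normal(0, config.noise_sd, config.n_samples)
        row[labels == cluster] += config.effect_size
        log_expr[gene_index[g]] = row
        annotations.append({"gene_id": g, "role": "signature", "cluster": cluster})
    for g in hk:
        # For small sigma a log-normal's CV is ~ sigma, so the log-sd is the
        # requested coefficient of variation directly.
        log_expr[gene_index[g]] = base[gene_index[g]] + rng.normal(
            0, config.housekeeping_cv, config.n_samples
        )
        annotations.append({"gene_id": g, "role": "housekeeping", "cluster": 0})
    for g in other:
        log_expr[gene_index[g]] = base[gene_index[g]] + rng.normal(
            0, config.noise_sd, config.n_samples
        )
        role = "target" if g in target_names else (
            "predictor" if g in predictor_names else "noise"
        )
        annotations.append({"gene_id": g, "role": role, "cluster": 0})

    # Overwrite target rows with the prescribed functional dependence.
    for t in config.imputation_targets:
        z = np.vstack(
            [
                log_expr[gene_index[p]] - log_expr[gene_index[p]].mean()
                for p in t.predictors
            ]
        )
        signal = z.sum(axis=0)
        if t.form == "interaction" and len(t.predictors) >= 2:
            signal = signal + z[0] * z[1]
        sd_signal = signal.std()
        if sd_signal == 0:
            raise ValueError(f"degenerate predictors for target {t.target}")
        noise_sd = sd_signal * np.sqrt((1.0 - t.true_r2) / t.true_r2)
        log_expr[gene_index[t.target]] = (
            base[gene_index[t.target]]
            + signal
            + rng.normal(0, noise_sd, config.n_samples)
        )

    expr = pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    expr.index.name = "gene_id"
    labels_s = pd.Series(labels, index=samples, name="cluster")
    ann = pd.DataFrame(annotations).set_index("gene_id")
    return expr, labels_s, ann


# ---------------------------------------------------------------------------
# Writers


def save_rgb_image(rgb: np.ndarray, path) -> None:
    """Write an RGB tile as PNG or TIFF, inferred from the suffix."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, np.asarray(rgb, dtype=np.uint8))
    else:
        from PIL import Image

        Image.fromarray(np.asarray(rgb, dtype=np.uint8)).save(path)


def save_label_mask(mask: np.ndarray, path) -> None:
    """Write a label mask as single-channel 16-bit TIFF."""
    import tifffile

    mask = np.asarray(mask)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 objects: cannot store as 16-bit")
    tifffile.imwrite(str(path), mask.astype(np.uint16))
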