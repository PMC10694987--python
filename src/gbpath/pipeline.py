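"""End-to-end orchestration of the image and expression arms.

The image arm chains deconvolution -> Otsu segmentation -> feature
extraction -> (optional) artifact filtering -> spatial statistics ->
morphology clustering over a batch of tiles described by a manifest. The
expression arm chains signature subsetting -> embedding -> silhouette
k-means -> permutation validation -> (when diagnosis labels exist) the 2x2
Yates chi-square. Every run derives per-stage seeds from one global seed and
writes a manifest of parameters alongside its outputs, so identical configs
reproduce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gbpath import (
    expression_clustering,
    feature_extraction,
    morphology_clustering,
    segmentation,
    spatial_stats,
    stain_deconvolution,
)

__all__ = ["PipelineConfig", "run_image_arm", "run_expression_arm", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGES = [
    "deconvolve", "segment", "features", "filter", "spatial", "morphocluster",
    "subset", "embed", "kmeans", "permutation", "chi2",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, collision-free)."""
    return (int(global_seed) * 1000 + _STAGES.index(stage)) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters plus I/O paths; strict on unknown keys.

    Defaults are the analysis conventions of the workflow this package
    implements: k = 100 for the nearest-neighbor statistic, 8,000 cells per
    group, a 160-cell minimum cluster size, 10,000 permutations, and the
    lower 20th variance percentile for housekeeping selection.
    """

    # image arm
    image_manifest: str = ""  # CSV: image_id, path, stain_panel, group, region
    stain_panel: str = "HDAB"
    otsu_bins: int = 256
    connectivity: int = 8
    min_area: float = 1.0
    knn_k: int = 100
    n_per_group: int = 8000
    min_cluster_size: int = 160
    dbscan_eps: float = 0.5
    dbscan_min_samples: int = 5
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    run_morphology: bool = True
    # expression arm
    expression_path: str = ""  # TSV/CSV, genes in rows, first column gene_id
    gene_list_path: str = ""  # plain text, one gene per line
    diagnosis_path: str = ""  # optional CSV: sample_id, diagnosis
    k_min: int = 2
    k_max: int = 10
    kmeans_n_init: int = 10
    n_perm: int = 10000
    n_sampled_pairs: int = 10000
    tsne_perplexity: float = 10.0
    # global
    seed: int = 0
    out_dir: str = "gbpath_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_rgb(path: str) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path))
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))


def _stain_matrix(panel: str) -> stain_deconvolution.StainMatrix:
    panels = {
        "HE": stain_deconvolution.HE_MATRIX,
        "HDAB": stain_deconvolution.HDAB_MATRIX,
    }
    if panel not in panels:
        raise ValueError(f"stain_panel must be one of {sorted(panels)}, got {panel!r}")
    return panels[panel]


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def process_image(
    rgb: np.ndarray, config: PipelineConfig, image_id: str = "",
    group: str = "", region: str = "",
) -> tuple[spatial_stats.ImageStatRecord, pd.DataFrame]:
    """Run one tile through deconvolution, segmentation, features and stats."""
    matrix = _stain_matrix(config.stain_panel)
    od = stain_deconvolution.rgb_to_od(rgb)
    conc = stain_deconvolution.deconvolve(od, matrix)
    hema = stain_deconvolution.stain_channel(conc, "hematoxylin")
    labels, _ = segmentation.segment_channel(
        hema, n_bins=config.otsu_bins, connectivity=config.connectivity
    )
    table = feature_extraction.extract_features(
        labels, hema, image_id=image_id, group=group, region=region
    )
    table = table[table["area"] >= config.min_area]

    record = spatial_stats.ImageStatRecord(
        image_id=image_id, group=group, region=region,
        n_cells=int(len(table)), k=config.knn_k,
    )
    knn = spatial_stats.knn_mean_distance(
        table[["cx", "cy"]].to_numpy(dtype=float), k=config.knn_k
    )
    record.mean_knn_distance = knn.mean
    record.flags["insufficient_cells"] = knn.insufficient_cells

    if config.stain_panel == "HDAB":
        dab = stain_deconvolution.stain_channel(conc, "dab")
        hema_mask = labels > 0
        try:
            t_dab = segmentation.otsu_threshold(dab, n_bins=config.otsu_bins)
            dab_mask = segmentation.binarize(dab, t_dab)
        except ValueError:
            dab_mask = np.zeros_like(hema_mask)
        ratio = spatial_stats.stain_pixel_ratio(dab_mask, hema_mask)
        record.dab_hema_ratio = ratio.ratio
        record.flags["zero_denominator"] = ratio.zero_denominator
    return record, table


def run_image_arm(config: PipelineConfig) -> dict:
    """Process every manifest image; write statistics CSV and clustering JSON."""
    manifest_path = Path(config.image_manifest)
    if not manifest_path.exists():
        raise FileNotFoundError(f"image manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError(f"image manifest {manifest_path} lists no images")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, tables = [], []
    for _, row in manifest.iterrows():
        image_id = str(row["image_id"])
        try:
            rgb = _load_rgb(row["path"])
            record, table = process_image(
                rgb, config, image_id=image_id,
                group=str(row.get("group", "")), region=str(row.get("region", "")),
            )
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise RuntimeError(
                f"image arm failed at image {image_id!r}: {exc}"
            ) from exc
        logger.info("image %s: %d cells retained", image_id, record.n_cells)
        records.append(record)
        tables.append(table)

    stats_df = pd.DataFrame(
        [
            {
                "image_id": r.image_id, "group": r.group, "region": r.region,
                "n_cells": r.n_cells, "k": r.k,
                "mean_knn_distance": r.mean_knn_distance,
                "dab_hema_ratio": r.dab_hema_ratio,
                **{f"flag_{k}": v for k, v in r.flags.items()},
            }
            for r in records
        ]
    )
    stats_df.to_csv(out / "image_stats.csv", index=False)
    cells = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    cells.to_csv(out / "cells.csv", index=False)

    result = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "n_images": len(records),
    }
    if config.run_morphology and not cells.empty:
        groups = cells["group"].value_counts()
        if len(groups) >= 2 and groups.min() >= config.n_per_group:
            morpho = morphology_clustering.run_morphology_clustering(
                cells, stain=config.stain_panel, eps=config.dbscan_eps,
                n_per_group=config.n_per_group,
                min_samples=config.dbscan_min_samples,
                min_cluster_size=config.min_cluster_size,
                n_neighbors=config.umap_n_neighbors,
                min_dist=config.umap_min_dist,
                seed=stage_seed(config.seed, "morphocluster"),
            )
            result["morphology"] = {
                "chi2_stat": morpho.chi2_stat, "df": morpho.chi2_df,
                "p": morpho.chi2_p,
                "contingency": morpho.contingency.to_dict(),
                "omitted_clusters": morpho.omitted_clusters,
            }
        else:
            result["morphology"] = "skipped: groups too small for balanced subsample"
    _write_json(result, out / "image_arm.json")
    return result


def load_expression(path) -> pd.DataFrame:
    """Read a genes x samples matrix (TSV or CSV, first column gene ids)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr = pd.read_csv(path, sep=sep, index_col=0)
    if expr.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return expr


def run_expression_arm(config: PipelineConfig) -> dict:
    """Subset -> embed -> silhouette k-means -> permutation -> chi-square."""
    expr = load_expression(config.expression_path)
    with open(config.gene_list_path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sub = expression_clustering.subset_signature(expr, genes)
    embedding = expression_clustering.embed_samples(
        sub, perplexity=config.tsne_perplexity,
        seed=stage_seed(config.seed, "embed"),
    )
    embedding.to_csv(out / "embedding.csv")
    assignment = expression_clustering.kmeans_silhouette(
        sub, k_range=range(config.k_min, config.k_max + 1),
        n_init=config.kmeans_n_init, seed=stage_seed(config.seed, "kmeans"),
    )
    perm = expression_clustering.permutation_cluster_test(
        sub, assignment, n_perm=config.n_perm,
        n_sampled_pairs=config.n_sampled_pairs,
        seed=stage_seed(config.seed, "permutation"),
    )
    result = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "k": assignment.k,
        "silhouette_by_k": assignment.silhouette_by_k["silhouette"].to_dict(),
        "cluster_sizes": assignment.labels.value_counts().to_dict(),
        "permutation": {
            "observed_within": perm.observed_within,
            "observed_between": perm.observed_between,
            "observed_separation": perm.observed_separation,
            "empirical_p": perm.empirical_p,
            "n_perm": perm.n_perm,
        },
    }
    assignment.labels.to_csv(out / "clusters.csv")

    if config.diagnosis_path:
        diagnosis = pd.read_csv(config.diagnosis_path, index_col=0).iloc[:, 0]
        shared = assignment.labels.index.intersection(diagnosis.index)
        table = pd.crosstab(assignment.labels.loc[shared], diagnosis.loc[shared])
        if table.shape == (2, 2):
            result["chi2_2x2_yates"] = expression_clustering.chi2_2x2_yates(
                table.to_numpy()
            )
            result["chi2_table"] = table.to_dict()
        else:
            result["chi2_2x2_yates"] = (
                f"skipped: table shape {table.shape} is not 2x2"
            )
    else:
        result["chi2_2x2_yates"] = "skipped: no diagnosis labels provided"
        logger.info("no diagnosis labels: chi-square step skipped")
    _write_json(result, out / "expression_arm.json")
    return result
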