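"""Ground-truthed synthetic image and expression generators."""

import numpy as np
import pandas as pd
import pytest

from gbpath import synthetic_data as sd


class TestImageGenerator:
    def test_deterministic(self):
        cfg = sd.ImageSimConfig(width=128, height=128, n_cells=20, seed=9)
        a = sd.generate_ihc_image(cfg)
        b = sd.generate_ihc_image(cfg)
        assert np.array_equal(a.rgb, b.rgb)
        assert np.array_equal(a.label_mask, b.label_mask)
        pd.testing.assert_frame_equal(a.truth.records, b.truth.records)

    def test_truth_counts_are_exact_recounts(self, noise_free_sim):
        sim = noise_free_sim
        assert sim.truth.true_dab_pixel_count == int((sim.dab_concentration > 0).sum())
        assert sim.truth.true_hematoxylin_pixel_count == int(
            (sim.hema_concentration > 0).sum()
        )
        # All nuclei carry hematoxylin, so DAB pixels are a subset.
        assert ((sim.dab_concentration > 0) <= (sim.hema_concentration > 0)).all()

    def test_label_mask_matches_hema_raster_when_no_artifacts(self, nonoverlap_sim):
        sim = nonoverlap_sim
        assert ((sim.label_mask > 0) == (sim.hema_concentration > 0)).all()
        assert sim.label_mask.max() == sim.config.n_cells

    def test_nonoverlap_objects_are_disjoint(self, nonoverlap_sim):
        truth = nonoverlap_sim.truth.records
        pts = truth[["cx", "cy"]].to_numpy()
        radii = truth["radius"].to_numpy()
        for i in range(len(pts)):
            d = np.hypot(*(pts[i] - pts[i + 1 :]).T)
            assert (d > radii[i] + radii[i + 1 :]).all()

    def test_overdense_nonoverlap_raises(self):
        cfg = sd.ImageSimConfig(
            width=64, height=64, n_cells=200, allow_overlap=False, seed=0
        )
        with pytest.raises(RuntimeError, match="without overlap"):
            sd.generate_ihc_image(cfg)

    def test_artifacts_in_truth_but_not_mask(self):
        cfg = sd.ImageSimConfig(
            width=256, height=256, n_cells=40, artifact_fraction=0.25, seed=2
        )
        sim = sd.generate_ihc_image(cfg)
        truth = sim.truth.records
        assert truth["is_artifact"].sum() == 10
        assert (truth.loc[truth["is_artifact"], "cell_id"] < 0).all()
        assert sim.label_mask.max() == 40  # artifacts carry no labels
        assert not truth.loc[truth["is_artifact"], "dab_positive"].any()

    def test_background_is_white(self, noise_free_sim):
        sim = noise_free_sim
        background = sim.hema_concentration == 0
        assert (sim.rgb[background] == 255).all()

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sd.ImageSimConfig(
                morphology_populations=[sd.MorphologyPopulation(0.5, 8, 1, 0.5)]
            )

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = sd.ImageSimConfig(
            n_cells=33, artifact_fraction=0.1,
            morphology_populations=[
                sd.MorphologyPopulation(0.4, 6.0, 1.0, 0.3),
                sd.MorphologyPopulation(0.6, 12.0, 2.0, 0.7),
            ],
            seed=17,
        )
        cfg.to_yaml(tmp_path / "c.yaml")
        loaded = sd.ImageSimConfig.from_yaml(tmp_path / "c.yaml")
        assert loaded == cfg

    def test_image_writers_round_trip(self, tmp_path, nonoverlap_sim):
        import tifffile
        from PIL import Image

        sim = nonoverlap_sim
        sd.save_rgb_image(sim.rgb, tmp_path / "tile.png")
        sd.save_label_mask(sim.label_mask, tmp_path / "mask.tiff")
        rgb = np.asarray(Image.open(tmp_path / "tile.png"))
        mask = tifffile.imread(tmp_path / "mask.tiff")
        assert np.array_equal(rgb, sim.rgb)
        assert np.array_equal(mask, sim.label_mask)


@pytest.fixture(scope="module")
def sim():
    cfg = sd.ExprSimConfig(
        n_samples=90, n_genes=120, k_clusters=3, signature_size=30,
        effect_size=1.5, n_housekeeping=5,
        imputation_targets=[
            sd.ImputationTargetSpec("gene_0001", ("gene_0002", "gene_0003"))
        ],
        seed=21,
    )
    return cfg, sd.generate_expression(cfg)


class TestExpressionGenerator:
    def test_shapes_names_positivity(self, sim):
        cfg, (expr, labels, ann) = sim
        assert expr.shape == (120, 90)
        assert (expr.to_numpy() > 0).all()
        assert len(labels) == 90
        assert sorted(labels.unique()) == [1, 2, 3]
        assert ann["role"].value_counts()["housekeeping"] == 5

    def test_clusters_balanced(self, sim):
        _, (_, labels, _) = sim
        assert labels.value_counts().tolist() == [30, 30, 30]

    def test_housekeeping_low_cv(self, sim):
        _, (expr, _, ann) = sim
        hk = ann.index[ann["role"] == "housekeeping"]
        cv = expr.loc[hk].std(axis=1) / expr.loc[hk].mean(axis=1)
        assert cv.max() < 0.05

    def test_signature_effect_present(self, sim):
        _, (expr, labels, ann) = sim
        log = np.log(expr)
        for g in ["sig_0001", "sig_0002", "sig_0003"]:
            cluster = int(ann.loc[g, "cluster"])
            inside = log.loc[g, labels == cluster].mean()
            outside = log.loc[g, labels != cluster].mean()
            assert inside - outside > 0.75  # effect_size=1.5, noise_sd=0.5

    def test_imputation_target_r2(self, sim):
        _, (expr, _, _) = sim
        log = np.log(expr)
        z = (
            (log.loc["gene_0002"] - log.loc["gene_0002"].mean())
            + (log.loc["gene_0003"] - log.loc["gene_0003"].mean())
        )
        r = np.corrcoef(z, log.loc["gene_0001"])[0, 1]
        assert r**2 > 0.75  # prescribed true_r2 = 0.9, n = 90

    def test_deterministic(self, sim):
        cfg, (expr, labels, _) = sim
        expr2, labels2, _ = sd.generate_expression(cfg)
        pd.testing.assert_frame_equal(expr, expr2)
        pd.testing.assert_series_equal(labels, labels2)

    def test_target_cannot_be_predictor(self):
        with pytest.raises(ValueError, match="own predictor"):
            sd.ImputationTargetSpec("gene_0001", ("gene_0001",))

    def test_reserved_genes_must_fit(self):
        with pytest.raises(ValueError, match="exceed n_genes"):
            sd.ExprSimConfig(n_genes=50, signature_size=45, n_housekeeping=10)
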