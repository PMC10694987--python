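"""Per-object shape, moment, intensity and texture features."""

import numpy as np
import pytest

from gbpath import feature_extraction as fe


class TestShapeFeatures:
    def test_square(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:5, 3:6] = 1  # 3x3 square
        row = fe.shape_features(labels).iloc[0]
        assert row["area"] == 9
        assert row["perimeter"] == 12
        # All 8 non-center pixels are boundary; center (3, 4) is interior.
        assert row["radius_min"] == 1.0
        assert row["radius_max"] == pytest.approx(np.sqrt(2))

    def test_single_pixel(self):
        labels = np.zeros((3, 3), dtype=np.int32)
        labels[1, 1] = 1
        row = fe.shape_features(labels).iloc[0]
        assert row["area"] == 1
        assert row["perimeter"] == 4
        assert row["radius_mean"] == 0.0

    def test_border_object_perimeter_counts_image_edge(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0:2, 0:2] = 1  # 2x2 in the corner
        assert fe.shape_features(labels).iloc[0]["perimeter"] == 8

    def test_disk_area_matches_continuum(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        rr, cc = np.ogrid[:64, :64]
        labels[(rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2] = 1
        row = fe.shape_features(labels).iloc[0]
        assert row["area"] == pytest.approx(np.pi * 400, rel=0.03)
        assert row["radius_mean"] == pytest.approx(20, rel=0.05)


class TestMomentFeatures:
    def test_square_centroid_and_zero_eccentricity(self):
        labels = np.zeros((24, 24), dtype=np.int32)
        labels[10:13, 10:13] = 1
        row = fe.moment_features(labels).iloc[0]
        assert (row["cx"], row["cy"]) == (11.0, 11.0)
        assert row["eccentricity"] == 0.0

    def test_horizontal_bar(self):
        labels = np.zeros((5, 25), dtype=np.int32)
        labels[2, 2:23] = 1  # 1x21 horizontal bar
        row = fe.moment_features(labels).iloc[0]
        assert row["theta"] == 0.0
        assert row["eccentricity"] > 0.99
        assert row["eccentricity"] < 1.0  # +1/12 term keeps it strictly below 1

    def test_vertical_bar_theta(self):
        labels = np.zeros((25, 5), dtype=np.int32)
        labels[2:23, 2] = 1
        row = fe.moment_features(labels).iloc[0]
        assert row["theta"] == pytest.approx(np.pi / 2)

    def test_diagonal_line_theta_sign(self):
        # Down-right diagonal: with y upward, orientation is -45 degrees.
        labels = np.diag(np.ones(15)).astype(np.int32)
        row = fe.moment_features(labels).iloc[0]
        assert row["theta"] == pytest.approx(-np.pi / 4)

    def test_major_axis_of_bar_matches_length(self):
        n = 21
        labels = np.zeros((3, n + 4), dtype=np.int32)
        labels[1, 2 : 2 + n] = 1
        row = fe.moment_features(labels).iloc[0]
        # A uniform segment of n unit pixels has lambda1 = n**2 / 12, so the
        # ellipse-equivalent axis 4*sqrt(lambda1) is 2n/sqrt(3).
        assert row["major_axis"] == pytest.approx(2 * n / np.sqrt(3), rel=1e-12)

    def test_ellipse_eccentricity_recovery(self, nonoverlap_sim):
        sim = nonoverlap_sim
        table = fe.moment_features(sim.label_mask).merge(
            sim.truth.records, left_on="object_id", right_on="cell_id"
        )
        err = (table["eccentricity_x"] - table["eccentricity_y"]).abs()
        assert err.max() < 0.05


class TestIntensityFeatures:
    def test_known_values(self):
        labels = np.zeros((2, 4), dtype=np.int32)
        labels[0] = 1
        channel = np.array([[0.0, 1.0, 2.0, 3.0], [9.0, 9.0, 9.0, 9.0]])
        row = fe.intensity_features(labels, channel).iloc[0]
        assert row["intensity_mean"] == 1.5
        assert row["intensity_sd"] == pytest.approx(np.sqrt(1.25))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            fe.intensity_features(np.zeros((2, 2), dtype=int), np.zeros((3, 3)))


class TestTextureFeatures:
    def test_checkerboard_contrast(self):
        labels = np.ones((8, 8), dtype=np.int32)
        channel = np.indices((8, 8)).sum(axis=0) % 2  # 0/1 checkerboard
        row = fe.texture_features(labels, channel.astype(float), levels=16).iloc[0]
        # Neighbors always differ by 15 quantized levels: contrast = 15**2.
        assert row["glcm_contrast"] == 225.0
        assert row["glcm_correlation"] == pytest.approx(-1.0)
        assert not row["glcm_degenerate"]

    def test_constant_object_is_flat_texture(self):
        labels = np.ones((4, 4), dtype=np.int32)
        row = fe.texture_features(labels, np.full((4, 4), 0.5)).iloc[0]
        assert row["glcm_contrast"] == 0.0
        assert row["glcm_energy"] == 1.0
        assert row["glcm_correlation"] == 1.0  # degenerate sd convention

    def test_single_pixel_object_degenerate(self):
        labels = np.zeros((3, 3), dtype=np.int32)
        labels[1, 1] = 1
        row = fe.texture_features(labels, np.ones((3, 3)) * 0.5).iloc[0]
        assert row["glcm_degenerate"]
        assert row["glcm_contrast"] == 0.0

    def test_pairs_outside_object_excluded(self):
        # Two-pixel object beside a very different background value: the
        # background must not leak into the co-occurrence counts.
        labels = np.zeros((3, 3), dtype=np.int32)
        labels[1, 0:2] = 1
        channel = np.ones((3, 3))  # background at top level
        channel[1, 0:2] = 0.5
        row = fe.texture_features(labels, channel).iloc[0]
        assert row["glcm_contrast"] == 0.0  # only the equal-value pair counts


class TestExtractFeatures:
    def test_column_contract_and_join(self, nonoverlap_sim):
        sim = nonoverlap_sim
        table = fe.extract_features(
            sim.label_mask, sim.hema_concentration, image_id="t1",
            group="PD", region="core",
        )
        assert len(table) == sim.label_mask.max()
        for col in (
            ["image_id", "object_id", "group", "region", "signal_label"]
            + fe.SHAPE_FEATURES + fe.MOMENT_FEATURES
            + fe.INTENSITY_FEATURES + fe.TEXTURE_FEATURES
        ):
            assert col in table.columns
        assert (table["signal_label"] == "unset").all()
        assert table["object_id"].tolist() == list(range(1, len(table) + 1))

    def test_empty_mask_gives_empty_table(self):
        table = fe.extract_features(np.zeros((5, 5), dtype=np.int32), np.zeros((5, 5)))
        assert table.empty
        assert "eccentricity" in table.columns

    def test_centroids_match_generator_truth(self, nonoverlap_sim):
        sim = nonoverlap_sim
        table = fe.extract_features(sim.label_mask, sim.hema_concentration)
        truth = sim.truth.records.set_index("cell_id")
        merged = table.set_index("object_id").join(truth, rsuffix="_true")
        assert (merged["cx"] - merged["cx_true"]).abs().max() < 1.0
        assert (merged["cy"] - merged["cy_true"]).abs().max() < 1.0
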