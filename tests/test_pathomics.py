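"""Tissue masking, patching, morphometry, NMF/CSDF, clustering, IHC unmixing."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import ellipse as draw_ellipse

import oracles
from radpath import pathomics
from radpath.synthetic import SceneSpec, generate_scene, scene_with_morphometrics


class TestTissueMask:
    def test_threshold_rule(self):
        img = np.zeros((2, 2, 3), np.uint8)
        img[0, 0] = (255, 255, 255)   # background
        img[0, 1] = (200, 220, 215)   # mean 211.67 -> background
        img[1, 0] = (100, 120, 110)   # tissue
        img[1, 1] = (210, 210, 210)   # mean exactly 210 -> tissue
        m = pathomics.tissue_mask(img)
        assert not m[0, 0] and not m[0, 1]
        assert m[1, 0] and m[1, 1]


class TestPatchify:
    def test_exact_grid(self):
        img = np.zeros((4096, 4096, 3), np.uint8)  # all dark = all tissue
        tiles = pathomics.patchify(img, patch=2048)
        assert len(tiles) == 4

    def test_all_white_image_no_tiles(self):
        img = np.full((4096, 4096, 3), 255, np.uint8)
        assert pathomics.patchify(img, patch=2048) == []

    def test_partial_edges_dropped(self):
        img = np.zeros((5000, 4100, 3), np.uint8)
        tiles = pathomics.patchify(img, patch=2048, edge_policy="drop")
        assert len(tiles) == 4  # 2 x 2 full tiles


class TestMorphometrics:
    def test_filled_square(self):
        labels = np.zeros((20, 20), np.uint16)
        labels[5:15, 5:15] = 1
        rgb = np.zeros((20, 20, 3), np.uint8)
        df = pathomics.nucleus_morphometrics(rgb, labels)
        assert df.loc[1, "area"] == 100
        assert df.loc[1, "aspect_ratio"] == pytest.approx(1.0, abs=0.01)

    def test_rendered_ellipse_axes_recovered(self):
        labels = np.zeros((128, 128), np.uint16)
        rr, cc = draw_ellipse(64, 64, 20, 10, shape=(128, 128))
        labels[rr, cc] = 1
        df = pathomics.nucleus_morphometrics(np.zeros((128, 128, 3)), labels)
        assert df.loc[1, "major_axis"] == pytest.approx(40, rel=0.05)
        assert df.loc[1, "minor_axis"] == pytest.approx(20, rel=0.05)
        assert df.loc[1, "aspect_ratio"] == pytest.approx(2.0, rel=0.08)

    def test_uniform_color_means_exact(self):
        labels = np.zeros((10, 10), np.uint16)
        labels[2:6, 2:6] = 1
        rgb = np.zeros((10, 10, 3), np.uint8)
        rgb[2:6, 2:6] = (50, 60, 70)
        df = pathomics.nucleus_morphometrics(rgb, labels)
        assert tuple(df.loc[1, ["mean_r", "mean_g", "mean_b"]]) == (50.0, 60.0, 70.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no nuclei"):
            pathomics.nucleus_morphometrics(
                np.zeros((5, 5, 3)), np.zeros((5, 5), np.uint16)
            )


class TestDelaunay:
    def test_equilateral_triangle(self):
        s = 10.0
        pts = np.array([[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]])
        df = pathomics.delaunay_distances(pts)
        np.testing.assert_allclose(df.to_numpy(), s, atol=1e-9)

    def test_unit_square_min_is_side(self):
        pts = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        df = pathomics.delaunay_distances(pts)
        np.testing.assert_allclose(df["delaunay_min"], 1.0, atol=1e-12)
        assert (df["delaunay_max"] <= np.sqrt(2) + 1e-12).all()

    def test_isometry_invariance(self, rng):
        pts = rng.random((30, 2)) * 100
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = pts @ rot.T + np.array([13.0, -4.0])
        d1 = pathomics.delaunay_distances(pts).to_numpy()
        d2 = pathomics.delaunay_distances(moved).to_numpy()
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_collinear_fallback_warns(self):
        pts = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        with pytest.warns(UserWarning, match="k-nearest"):
            df = pathomics.delaunay_distances(pts)
        assert df.loc[0, "delaunay_min"] == 1.0


class TestAggregateNmf:
    def _table(self, values):
        n = len(values)
        return pd.DataFrame(
            {c: values if c == "area" else np.asarray(values) * 0 + 1.0
             for c in pathomics.NMF_BASE_FEATURES}
        )

    def test_vector_length_150_and_names(self, rng):
        tab = self._table(rng.random(20))
        v = pathomics.aggregate_nmf(tab)
        assert len(v) == 150
        assert v.filter(like="area_hist").shape[0] == 10

    def test_histograms_normalized_entropy_bounded(self, rng):
        tab = self._table(rng.random(50))
        v = pathomics.aggregate_nmf(tab)
        for feat in pathomics.NMF_BASE_FEATURES:
            h = v[[f"{feat}_hist{b}" for b in range(1, 11)]]
            assert h.sum() == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= v[f"{feat}_entropy"] <= np.log2(10) + 1e-12

    def test_identical_nuclei_degenerate(self):
        tab = self._table([3.0] * 8)
        v = pathomics.aggregate_nmf(tab)
        assert v["area_sd"] == 0.0
        assert v["area_hist1"] == 1.0
        assert v["area_entropy"] == 0.0

    def test_uniform_fill_max_entropy(self):
        # 10 values, one per bin
        tab = self._table(np.arange(10) + 0.5)
        v = pathomics.aggregate_nmf(tab)
        assert v["area_entropy"] == pytest.approx(np.log2(10))

    def test_moment_arithmetic(self):
        tab = self._table([1.0, 2.0, 3.0, 4.0])
        v = pathomics.aggregate_nmf(tab)
        assert v["area_mean"] == pytest.approx(2.5)
        assert v["area_sd"] == pytest.approx(np.sqrt(1.25))
        assert v["area_skewness"] == pytest.approx(0.0, abs=1e-12)
        assert v["area_kurtosis"] == pytest.approx(-1.36)


class TestCsdf:
    def test_basic_arithmetic(self):
        tissue = np.zeros((200, 200), bool)
        tissue[:100, :100] = True  # 10^4 px
        nuclei = pd.DataFrame(
            {"area": [50.0] * 10, "centroid_y": range(10), "centroid_x": range(10)}
        )
        count, density, proportion = pathomics.csdf_basic(nuclei, tissue)
        assert count == 10
        assert density == pytest.approx(1e-3)
        assert proportion == pytest.approx(0.05)

    def test_zero_nuclei(self):
        tissue = np.ones((10, 10), bool)
        out = pathomics.csdf_basic(pd.DataFrame({"area": []}), tissue)
        assert out == (0, 0.0, 0.0)

    def test_vector_length_12(self, rng):
        pts = rng.random((30, 2)) * 100
        nuclei = pd.DataFrame(
            {"area": rng.random(30) * 40 + 10,
             "centroid_y": pts[:, 0], "centroid_x": pts[:, 1]}
        )
        v = pathomics.csdf_vector(nuclei, np.ones((100, 100), bool))
        assert len(v) == 12

    def test_cluster_features_hand_arithmetic(self):
        pts = np.array([[0.0, 0], [0, 2], [10, 0], [10, 2]])
        labels = np.array([0, 0, 1, 1])
        f = pathomics.csdf_cluster_features(pts, labels)
        assert f["n_clusters"] == 2
        assert f["cluster_size_mean"] == 2
        assert f["dispersion_mean"] == pytest.approx(1.0)
        assert f["extent_mean"] == pytest.approx(2.0)
        assert f["ball_hall"] == pytest.approx(1.0)
        assert f["calinski_harabasz"] == pytest.approx(50.0)

    def test_ch_and_bh_match_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        pts = rng.random((40, 2)) * 50
        labels = rng.integers(0, 3, 40)
        f = pathomics.csdf_cluster_features(pts, labels)
        assert f["calinski_harabasz"] == pytest.approx(
            oracles.calinski_harabasz_brute(pts, labels), abs=1e-9
        )
        assert f["calinski_harabasz"] == pytest.approx(
            calinski_harabasz_score(pts, labels), rel=1e-9
        )
        assert f["ball_hall"] == pytest.approx(
            oracles.ball_hall_brute(pts, labels), abs=1e-9
        )

    def test_singleton_clusters_zero_dispersion(self):
        pts = np.array([[0.0, 0], [5, 5], [10, 10]])
        f = pathomics.csdf_cluster_features(pts, np.arange(3))
        assert f["dispersion_mean"] == 0.0
        assert f["extent_mean"] == 0.0
        assert f["ball_hall"] == 0.0

    def test_single_cluster_ch_flagged_zero(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 0]])
        f = pathomics.csdf_cluster_features(pts, np.zeros(3, int))
        assert f["calinski_harabasz"] == 0.0


class TestBirch:
    def test_two_separated_groups(self, rng):
        a = rng.normal(0, 1, (40, 2))
        b = rng.normal(40, 1, (40, 2))  # separation 40 >= 20x spread
        pts = np.vstack([a, b])
        labels = pathomics.birch_cluster(pts)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:40])) == 1
        assert len(np.unique(labels[40:])) == 1

    def test_single_blob_one_cluster(self, rng):
        pts = rng.normal(0, 1.0, (60, 2))
        labels = pathomics.birch_cluster(pts)
        assert len(np.unique(labels)) == 1

    def test_identical_points_one_cluster(self):
        pts = np.ones((10, 2))
        assert len(np.unique(pathomics.birch_cluster(pts))) == 1

    def test_order_invariance(self, rng):
        a = rng.normal(0, 1, (30, 2))
        b = rng.normal(30, 1, (30, 2))
        pts = np.vstack([a, b])
        perm = rng.permutation(len(pts))
        l1 = pathomics.birch_cluster(pts, threshold=3.0)
        l2 = pathomics.birch_cluster(pts[perm], threshold=3.0)
        # same partition up to label names
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_planted_four_cluster_scene_recovered(self):
        spec = SceneSpec(
            canvas=(768, 768), n_clusters=4, cells_per_cluster=18,
            cluster_spread=15.0, min_center_separation=150.0, seed=21,
        )
        _, _, table = scene_with_morphometrics(spec)
        pts = table[["centroid_y", "centroid_x"]].to_numpy()
        truth = table["cluster"].to_numpy()
        labels = pathomics.birch_cluster(pts)
        assert len(np.unique(labels)) == 4
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0


class TestColorDeconvolution:
    HE = np.array([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]])

    def _render(self, density, stain):
        od = density * stain / np.linalg.norm(stain)
        rgb = 256.0 * 10.0 ** (-od) - 1.0
        return np.clip(rgb, 0, 255)

    def test_pure_stain_pixel_unmixes_cleanly(self):
        px = self._render(1.0, self.HE[0])[None, None, :]
        dens, _ = pathomics.color_deconvolution(px, self.HE, positive_threshold=0.5)
        assert dens[0, 0, 0] == pytest.approx(1.0, abs=0.05)
        assert abs(dens[0, 0, 1]) < 0.05

    def test_white_pixel_near_zero_density(self):
        px = np.full((1, 1, 3), 255.0)
        dens, _ = pathomics.color_deconvolution(px, self.HE, positive_threshold=0.5)
        assert np.abs(dens).max() < 0.01

    def test_known_positive_fraction_recovered(self, rng):
        h, w = 64, 64
        frac = 0.25
        pos = rng.random((h, w)) < frac
        img = np.where(
            pos[..., None], self._render(1.0, self.HE[1]), self._render(1.0, self.HE[0])
        )
        _, mask = pathomics.color_deconvolution(img, self.HE)
        assert mask.mean() == pytest.approx(frac, abs=0.02)

    def test_collinear_stains_rejected(self):
        with pytest.raises(ValueError, match="collinear|singular"):
            pathomics.color_deconvolution(
                np.zeros((2, 2, 3)), np.array([[1.0, 0, 0], [2.0, 0, 0]])
            )


class TestRegistration:
    def test_zero_shift_for_identical(self, rng):
        img = rng.random((64, 64))
        (dy, dx), ok = pathomics.register_translation(img, img)
        assert (dy, dx) == (0.0, 0.0) and ok

    def test_known_shift_recovered(self, rng):
        img = rng.random((96, 96))
        moved = np.roll(np.roll(img, 5, axis=0), -3, axis=1)  # displaced (5, -3)
        (dy, dx), ok = pathomics.register_translation(img, moved)
        assert ok
        assert abs(dy - 5) <= 1 and abs(dx - (-3)) <= 1

    def test_brightness_offset_invariant(self, rng):
        img = rng.random((64, 64))
        moved = np.roll(img, 4, axis=0) + 0.5
        (dy, _), ok = pathomics.register_translation(img, moved)
        assert abs(dy - 4) <= 1

    def test_flat_images_flagged(self):
        (dy, dx), ok = pathomics.register_translation(
            np.ones((32, 32)), np.ones((32, 32))
        )
        assert (dy, dx) == (0.0, 0.0) and not ok


class TestFullSlideVector:
    def test_162_features_per_scene(self):
        rgb, labels, _ = generate_scene(SceneSpec(seed=12))
        nmf, csdf, table = pathomics.nmf_csdf_features(rgb, labels)
        assert len(nmf) == 150
        assert len(csdf) == 12
        assert len(nmf) + len(csdf) == 162
        # per-nucleus table carries exactly the 10 morphological quantities
        assert [c for c in table.columns if c in pathomics.NMF_BASE_FEATURES] == \
            list(pathomics.NMF_BASE_FEATURES)

    def test_planted_nucleus_axes_recovered(self):
        spec = SceneSpec(seed=13, major_axis=(14.0, 0.5), minor_axis=(7.0, 0.5))
        _, labels, table = scene_with_morphometrics(spec)
        assert table["major_axis"].mean() == pytest.approx(14.0, rel=0.08)
        assert table["minor_axis"].mean() == pytest.approx(7.0, rel=0.08)
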