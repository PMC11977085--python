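import numpy as np
import pytest

from conftest import random_region
from oracles import first_order_oracle, glszm_oracle, ngtdm_oracle

from renoct.features import (
    ExtractionConfig,
    apply_image_filter,
    discretize,
    extract_feature_table,
    feature_columns,
    filter_bank,
    first_order_features,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_matrix,
    parse_feature_name,
    shape_features,
)
from renoct.features.firstorder import EmptyRegionError
from renoct.imaging import CTVolume, SegmentationMask, region_volume_ml


class TestDiscretize:
    def test_formula(self):
        assert discretize(np.array([0.0, 0.5, 1.0]), 0.5).tolist() == [1, 2, 3]

    def test_constant_region_single_level(self):
        assert set(discretize(np.full(10, 3.3), 0.25)) == {1}

    def test_halving_bin_width_doubles_levels(self):
        # dense samples occupy every bin, so halving the width doubles (+-1)
        # the occupied-level count
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0, 5, size=3000)
            n1 = len(np.unique(discretize(x, 0.5)))
            n2 = len(np.unique(discretize(x, 0.25)))
            assert abs(n2 - 2 * n1) <= 1
            assert n2 <= int((x.max() - x.min()) / 0.25) + 1

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegionError):
            discretize(np.array([]), 0.5)


class TestFilters:
    def test_square_of_zero_volume_is_zero(self):
        out = apply_image_filter(np.zeros((4, 4, 4)), "square")["square"]
        assert np.all(out == 0)

    def test_gradient_of_constant_is_zero(self):
        out = apply_image_filter(np.full((6, 6, 6), 7.0), "gradient")["gradient"]
        assert np.allclose(out, 0)

    def test_wavelet_yields_eight_subbands_summing_to_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 12, 8))
        bands = apply_image_filter(x, "wavelet")
        assert len(bands) == 8
        assert all(b.shape == x.shape for b in bands.values())
        # single-level decomposition reconstructs the original
        assert np.allclose(sum(bands.values()), x, atol=1e-8)

    def test_sign_preservation(self):
        x = np.linspace(-2, 2, 64).reshape(4, 4, 4)
        for name in ("square", "logarithm"):
            out = apply_image_filter(x, name)[name]
            assert np.all(np.sign(out) == np.sign(x))

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            apply_image_filter(np.zeros((4, 4, 4)), "laplacian")


class TestFirstOrder:
    def test_single_voxel_total_energy(self):
        vals = first_order_features(np.array([2.0]), voxel_volume=2.0)
        assert vals["TotalEnergy"] == pytest.approx(8.0)
        assert vals["Energy"] == pytest.approx(4.0)

    def test_total_energy_is_voxel_volume_times_energy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        vals = first_order_features(x, voxel_volume=11.25)
        assert vals["TotalEnergy"] == pytest.approx(11.25 * vals["Energy"])

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        got = first_order_features(x, voxel_volume=3.5, bin_width=0.25)
        want = first_order_oracle(x, 3.5, 0.25)
        for name, v in want.items():
            assert got[name] == pytest.approx(v, abs=1e-10, rel=1e-10), name


class TestGLSZM:
    def test_1d_strip_worked_example(self):
        levels = np.array([[[1, 1, 2]]])
        mask = np.ones_like(levels, dtype=bool)
        feats = glszm_features(glszm_matrix(levels, mask))
        assert feats["SizeZoneNonUniformity"] == pytest.approx(1.0)
        assert feats["LargeAreaHighGrayLevelEmphasis"] == pytest.approx(4.0)

    def test_constant_region_single_zone(self):
        k = 3 * 4 * 2
        levels = np.ones((3, 4, 2), dtype=np.int64)
        mask = np.ones_like(levels, dtype=bool)
        m = glszm_matrix(levels, mask)
        assert m.n_zones == 1
        feats = glszm_features(m)
        assert feats["SizeZoneNonUniformity"] == pytest.approx(1.0)
        assert feats["LargeAreaHighGrayLevelEmphasis"] == pytest.approx(k**2)

    def test_matrix_sums_to_zone_count(self):
        rng = np.random.default_rng(4)
        levels, mask = random_region(rng)
        m = glszm_matrix(levels, mask)
        assert m.counts.sum() == m.n_zones == len(
            __import__("oracles").enumerate_zones(levels, mask)
        )

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        levels, mask = random_region(rng, shape=(6, 5, 4))
        got = glszm_features(glszm_matrix(levels, mask))
        want = glszm_oracle(levels, mask)
        for name, v in want.items():
            assert got[name] == pytest.approx(v, rel=1e-10), name


class TestNGTDM:
    def test_single_level_busyness_zero(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones_like(levels, dtype=bool)
        feats = ngtdm_features(ngtdm_matrix(levels, mask))
        assert feats["Busyness"] == 0.0
        assert feats["Contrast"] == 0.0

    def test_checkerboard_matches_oracle(self):
        idx = np.indices((3, 3, 1)).sum(axis=0)
        levels = (idx % 2) + 1
        mask = np.ones_like(levels, dtype=bool)
        got = ngtdm_features(ngtdm_matrix(levels, mask))
        want = ngtdm_oracle(levels, mask)
        for name, v in want.items():
            assert got[name] == pytest.approx(v, abs=1e-10, rel=1e-10), name

    def test_level_shift_behaviour_matches_oracle(self):
        rng = np.random.default_rng(6)
        levels, mask = random_region(rng, shape=(5, 5, 3))
        shifted = np.where(mask, levels + 3, 0)
        got = ngtdm_features(ngtdm_matrix(shifted, mask))
        want = ngtdm_oracle(shifted, mask)
        for name, v in want.items():
            assert got[name] == pytest.approx(v, rel=1e-10), name


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert feats["VoxelVolume"] == pytest.approx(1.0)

    def test_ball_sphericity_near_one(self):
        r = 10.0
        coords = np.meshgrid(*[np.arange(24) + 0.5] * 3, indexing="ij")
        q = sum((c - 12.0) ** 2 for c in coords)
        mask = q <= r**2
        feats = shape_features(mask, (1.0, 1.0, 1.0))
        assert 0.9 <= feats["Sphericity"] <= 1.0
        # mesh volume close to (4/3) pi r^3
        assert feats["MeshVolume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)

    def test_spacing_scales_diameter(self):
        rng = np.random.default_rng(7)
        mask = rng.random((8, 8, 6)) < 0.3
        mask[4, 4, 3] = True
        a = shape_features(mask, (1.0, 1.0, 1.0))
        b = shape_features(mask, (2.0, 2.0, 2.0))
        assert b["Maximum3DDiameter"] == pytest.approx(2 * a["Maximum3DDiameter"])
        assert b["MajorAxisLength"] == pytest.approx(2 * a["MajorAxisLength"])

    def test_voxel_volume_consistent_with_region_volume(self):
        labels = np.zeros((10, 10, 6), dtype=np.uint8)
        labels[2:8, 2:8, 1:5] = 1
        m = SegmentationMask(labels, (1.5, 1.5, 5.0), "left")
        feats = shape_features(labels == 1, m.spacing)
        assert feats["VoxelVolume"] == pytest.approx(1000 * region_volume_ml(m, 1))


class TestExtraction:
    @staticmethod
    def _toy_patient(seed=0, with_hydro=True):
        rng = np.random.default_rng(seed)
        vox = rng.normal(0, 1, (20, 16, 10))
        labels = np.zeros((20, 16, 10), dtype=np.uint8)
        labels[4:14, 4:12, 2:8] = 1
        if with_hydro:
            labels[8:11, 7:10, 4:6] = 2
        vol = CTVolume(vox, (1.5, 1.5, 5.0))
        mask = SegmentationMask(labels, (1.5, 1.5, 5.0), "left")
        return vol, mask

    def test_first_order_only_column_count(self):
        vol, mask = self._toy_patient()
        cfg = ExtractionConfig(families=("firstorder",), filters=("original",))
        df = extract_feature_table(vol, [mask], cfg)
        assert len(feature_columns(df)) == 2 * 18

    def test_empty_hydronephrosis_zero_filled_with_flag(self):
        vol, mask = self._toy_patient(with_hydro=False)
        cfg = ExtractionConfig(filters=("original",))
        df = extract_feature_table(vol, [mask], cfg)
        assert df["hydronephrosis_present"].iloc[0] == 0.0
        hydro_cols = [c for c in feature_columns(df) if "__hydronephrosis__" in c]
        assert hydro_cols and (df[hydro_cols].iloc[0] == 0).all()

    def test_missing_parenchyma_errors(self):
        vol, mask = self._toy_patient()
        empty = SegmentationMask(np.zeros_like(mask.labels), mask.spacing, "left")
        with pytest.raises(ValueError, match="parenchyma"):
            extract_feature_table(vol, [empty], ExtractionConfig(filters=("original",)))

    def test_default_config_includes_named_descriptors(self):
        vol, mask = self._toy_patient()
        df = extract_feature_table(vol, [mask], ExtractionConfig())
        for col in (
            "original__parenchyma__glszm_LargeAreaHighGrayLevelEmphasis",
            "original__parenchyma__firstorder_TotalEnergy",
            "original__parenchyma__glszm_SizeZoneNonUniformity",
            "original__parenchyma__ngtdm_Busyness",
            "original__hydronephrosis__ngtdm_Busyness",
        ):
            assert col in df.columns

    def test_axis_permutation_invariance(self):
        # intensity features must not depend on array layout
        vol, mask = self._toy_patient(seed=9)
        cfg = ExtractionConfig(families=("firstorder", "glszm", "ngtdm"), filters=("original", "gradient"))
        df = extract_feature_table(vol, [mask], cfg)
        perm = (2, 0, 1)
        vol_t = CTVolume(np.transpose(vol.voxels, perm), tuple(vol.spacing[i] for i in perm))
        mask_t = SegmentationMask(
            np.transpose(mask.labels, perm), vol_t.spacing, "left"
        )
        df_t = extract_feature_table(vol_t, [mask_t], cfg)
        a = df[feature_columns(df)].iloc[0].to_numpy()
        b = df_t[feature_columns(df_t)].iloc[0].to_numpy()
        assert np.allclose(a, b, rtol=1e-8)

    def test_parse_feature_name_roundtrip(self):
        d = parse_feature_name("wavelet-LLH__parenchyma__glszm_ZoneEntropy")
        assert (d.filter, d.region, d.family, d.feature) == (
            "wavelet-LLH",
            "parenchyma",
            "glszm",
            "ZoneEntropy",
        )
        with pytest.raises(ValueError):
            parse_feature_name("hydronephrosis_present")
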