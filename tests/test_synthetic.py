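"""Generator contracts: determinism, counts, ground-truth consistency,
render identities, and the analytic fractal fixtures."""

import numpy as np
import pytest

from plaquemetrics import synthetic, vascular
from plaquemetrics.errors import DataError, UsageError
from plaquemetrics.io import ImagePlane
from plaquemetrics.segmentation import separate_stains


class TestGenerateScene:
    def test_empty_scene(self):
        spec = synthetic.SceneSpec(n_plaques=0, vessel_count=0, seed=1)
        scene, gt = synthetic.generate_scene(spec)
        assert not scene.plaque_labels.any()
        assert not scene.vessel_mask.any()
        assert len(gt.plaques) == 0
        assert list(gt.plaques.columns) == synthetic.GT_COLUMNS

    def test_determinism_bit_identical(self):
        spec = synthetic.SceneSpec(n_plaques=12, seed=3)
        s1, g1 = synthetic.generate_scene(spec)
        s2, g2 = synthetic.generate_scene(synthetic.SceneSpec(n_plaques=12, seed=3))
        assert np.array_equal(s1.dab_density, s2.dab_density)
        assert np.array_equal(s1.vessel_mask, s2.vessel_mask)
        assert g1.plaques.equals(g2.plaques)
        b1 = synthetic.render_brightfield(s1)
        b2 = synthetic.render_brightfield(s2)
        assert np.array_equal(b1.data, b2.data)

    def test_plaque_count_contract(self):
        spec = synthetic.SceneSpec(n_plaques=25, seed=7)
        _, gt = synthetic.generate_scene(spec)
        assert len(gt.plaques) == 25
        assert gt.plaques["id"].is_unique
        assert (gt.plaques["area_um2"] > 0).all()

    def test_contact_flag_iff_zero_distance(self, noiseless_scene):
        _, gt = noiseless_scene
        t = gt.plaques
        assert (t.loc[t["contact"], "nearest_vessel_distance_um"] == 0).all()
        assert (t.loc[~t["contact"], "nearest_vessel_distance_um"] > 0).all()

    def test_field_too_small_raises(self):
        with pytest.raises(DataError, match="too small"):
            synthetic.SceneSpec(
                field_size_px=(32, 32), diameter_range_um=(30.0, 60.0)
            ).validate()

    def test_mix_must_sum_to_one(self):
        spec = synthetic.SceneSpec(
            plaque_type_mix={"diffuse": 0.5, "dense": 0.2, "dense_core": 0.2}
        )
        with pytest.raises(DataError, match="sum to 1"):
            spec.validate()

    def test_plaque_masks_disjoint_and_bounded(self, noiseless_scene):
        scene, gt = noiseless_scene
        # label raster enforces disjointness; total true area fits the field
        field_um2 = scene.plaque_labels.size * scene.spec.pixel_size_um**2
        assert gt.plaques["area_um2"].sum() <= field_um2
        labeled_px = int((scene.plaque_labels > 0).sum())
        expected_px = gt.plaques["area_um2"].sum() / scene.spec.pixel_size_um**2
        assert labeled_px == int(round(expected_px))

    def test_gt_distances_match_vascular_module(self, noiseless_scene):
        """Recomputing nearest-vessel distances from the emitted masks
        reproduces the ground truth within one pixel-equivalent."""
        scene, gt = noiseless_scene
        px = scene.spec.pixel_size_um
        for _, row in gt.plaques.iterrows():
            mask = scene.plaque_labels == row["id"]
            d, contact = vascular.nearest_vessel_distance(mask, scene.vessel_mask, px)
            assert contact == row["contact"]
            assert d == pytest.approx(row["nearest_vessel_distance_um"], abs=px)

    def test_fibrillar_core_fraction(self):
        spec = synthetic.SceneSpec(n_plaques=20, fibrillar_core_fraction=0.5, seed=11)
        scene, gt = synthetic.generate_scene(spec)
        t = gt.plaques
        eligible = t["type"].isin(["dense", "dense_core"])
        assert t.loc[~eligible, "has_fibrillar_core"].sum() == 0
        assert t["has_fibrillar_core"].sum() == round(0.5 * eligible.sum())
        assert scene.fibrillar_core_mask.any() == bool(t["has_fibrillar_core"].any())


class TestRenderBrightfield:
    def test_zero_density_uniform_white(self, default_profile):
        spec = synthetic.SceneSpec(n_plaques=0, vessel_count=0, seed=1, noise_sd=0.0)
        scene, _ = synthetic.generate_scene(spec)
        scene.hematoxylin_density[:] = 0.0
        img = synthetic.render_brightfield(scene, default_profile, noise_sd=0.0)
        assert img.data.dtype == np.uint8
        # code 255 represents the transmitted white level (code + 1 = 256)
        assert (img.data == 255).all()

    def test_single_dab_pixel_roundtrip(self, default_profile):
        spec = synthetic.SceneSpec(
            field_size_px=(8, 8), diameter_range_um=(1, 2), n_plaques=0,
            vessel_count=0, seed=1, noise_sd=0.0,
        )
        scene, _ = synthetic.generate_scene(spec)
        scene.hematoxylin_density[:] = 0.0
        scene.dab_density[4, 4] = 1.0
        img = synthetic.render_brightfield(scene, default_profile, noise_sd=0.0)
        maps = separate_stains(img, default_profile)
        assert maps.dab[4, 4] == pytest.approx(1.0, abs=0.01)
        assert maps.hematoxylin[4, 4] <= 0.01
        assert maps.fast_red[4, 4] <= 0.01

    def test_od_log_linearity(self, default_profile):
        """Doubling DAB density doubles its projected optical density."""
        dab_vec = default_profile.dab
        for bit_depth in (8, 16):
            spec = synthetic.SceneSpec(
                field_size_px=(8, 8), diameter_range_um=(1, 2), n_plaques=0,
                vessel_count=0, seed=1, noise_sd=0.0,
            )
            scene, _ = synthetic.generate_scene(spec)
            scene.hematoxylin_density[:] = 0.0
            scene.dab_density[2, 2] = 0.4
            scene.dab_density[5, 5] = 0.8
            img = synthetic.render_brightfield(
                scene, default_profile, noise_sd=0.0, bit_depth=bit_depth
            )
            white = default_profile.white_level * (256 if bit_depth == 16 else 1)
            od = -np.log10((img.data.astype(float) + 1.0) / white)
            proj = od @ dab_vec
            tol = 0.02 if bit_depth == 8 else 1e-4  # quantization-limited
            assert proj[5, 5] == pytest.approx(2 * proj[2, 2], rel=tol)


class TestRenderFluorescence:
    def test_overlap_one_channels_identical(self, noiseless_scene):
        scene, _ = noiseless_scene
        img = synthetic.render_fluorescence(scene, overlap=1.0, noise_sd=0.0)
        assert np.array_equal(img.channel("ab40"), img.channel("ab42"))

    def test_overlap_zero_disjoint_supports(self, noiseless_scene):
        scene, _ = noiseless_scene
        img = synthetic.render_fluorescence(scene, overlap=0.0, noise_sd=0.0)
        a = img.channel("ab40") > 90
        b = img.channel("ab42") > 90
        assert a.any() and b.any()
        assert not (a & b).any()

    def test_ab42_covers_every_plaque(self, noiseless_scene):
        scene, _ = noiseless_scene
        img = synthetic.render_fluorescence(scene, noise_sd=0.0)
        b = img.channel("ab42") > 90
        assert (b & (scene.plaque_labels > 0)).sum() == (scene.plaque_labels > 0).sum()


class TestFractalMasks:
    def test_line_construction(self):
        m = synthetic.generate_fractal_mask("line", 128)
        assert m.sum() == 128 and m.shape[0] == 1

    def test_filled_square_construction(self):
        m = synthetic.generate_fractal_mask("filled_square", 64)
        assert m.shape == (64, 64) and m.all()

    def test_sierpinski_triangle_pixel_count(self):
        m = synthetic.generate_fractal_mask("sierpinski_triangle", 7)
        assert m.shape == (128, 128)
        assert int(m.sum()) == 3**7

    def test_sierpinski_carpet_pixel_count(self):
        m = synthetic.generate_fractal_mask("sierpinski_carpet", 4)
        assert m.shape == (81, 81)
        assert int(m.sum()) == 8**4

    def test_unknown_kind(self):
        with pytest.raises(UsageError, match="unknown fractal kind"):
            synthetic.generate_fractal_mask("koch", 5)

    def test_depth_floor(self):
        with pytest.raises(UsageError, match="depth"):
            synthetic.generate_fractal_mask("sierpinski_triangle", 3)


class TestStainProfile:
    def test_default_vectors_unit_norm(self, default_profile):
        for v in (default_profile.hematoxylin, default_profile.dab, default_profile.fast_red):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-6)
            assert (v >= 0).all()

    def test_dependent_vectors_rejected(self):
        v = np.array([0.6, 0.6, np.sqrt(1 - 2 * 0.36)])
        with pytest.raises(DataError, match="dependent"):
            synthetic.StainProfile(hematoxylin=v, dab=v, fast_red=v)


def test_simulated_records_hit_target_correlation():
    df = synthetic.simulate_plaque_vessel_records(2000, rho=-0.2, seed=5)
    r = np.corrcoef(df["max_diameter_um"], df["nearest_vessel_distance_um"])[0, 1]
    assert r == pytest.approx(-0.2, abs=0.06)
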