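"""Feature extraction: closed-form shapes, oracle equivalence, invariances."""

import numpy as np
import pytest
from oracles import (
    dt_fractions_loop,
    glcm_loop,
    glcm_stats_loop,
    moments_loop,
    rl_stats_loop,
    rlm_loop,
)

from nucrisk.qnp import (
    NuclearObject,
    RL_DIRECTIONS,
    compute_qnp,
    cooccurrence_features,
    discrete_texture_features,
    fractal_and_radial_features,
    morphology_features,
    object_from_mask,
    photometric_features,
    quantize,
    run_length_matrix,
    runlength_features,
)
from nucrisk.registry import default_registry


def disk_mask(r, pad=2):
    size = 2 * (r + pad) + 1
    y, x = np.mgrid[:size, :size]
    return (y - r - pad) ** 2 + (x - r - pad) ** 2 <= r**2


def make_object(mask, od=None, pixel_size=1.0):
    od = np.full(mask.shape, 0.5) if od is None else od
    return object_from_mask(mask, np.where(mask, od, 0.0), pixel_size=pixel_size)


def random_object(rng, size=12):
    """Random connected blob with random OD, <=16x16."""
    mask = disk_mask(size // 2 - 1)[:size, :size]
    od = rng.uniform(0.05, 1.5, mask.shape)
    return make_object(mask, od)


class TestMorphology:
    def test_disk_compactness_near_isoperimetric_limit(self):
        feats = morphology_features(make_object(disk_mask(30)))
        assert 0.95 <= feats["compactness"] <= 1.05

    def test_square_compactness(self):
        mask = np.zeros((60, 60), bool)
        mask[5:55, 5:55] = True
        feats = morphology_features(make_object(mask))
        assert feats["compactness"] == pytest.approx(np.pi / 4, abs=0.05)

    def test_ellipse_eccentricity(self):
        y, x = np.mgrid[:50, :140]
        mask = ((y - 25) / 15) ** 2 + ((x - 70) / 60) ** 2 <= 1  # 4:1 axes
        feats = morphology_features(make_object(mask))
        assert feats["eccentricity"] == pytest.approx(np.sqrt(1 - 1 / 16), abs=0.01)
        assert feats["elongation"] == pytest.approx(4.0, rel=0.05)

    def test_area_in_physical_units(self):
        mask = disk_mask(20)
        a1 = morphology_features(make_object(mask, pixel_size=0.25))["area_um2"]
        a2 = morphology_features(make_object(mask, pixel_size=0.5))["area_um2"]
        assert a2 == pytest.approx(4 * a1)


class TestPhotometric:
    def test_uniform_patch_exact(self):
        mask = disk_mask(6)
        obj = make_object(mask, np.full(mask.shape, 0.37))
        feats = photometric_features(obj)
        assert feats["iod"] == pytest.approx(0.37 * mask.sum(), abs=1e-12)
        assert feats["od_var"] == 0.0
        assert feats["od_skew"] == 0.0

    def test_od_scaling(self, rng):
        mask = disk_mask(6)
        od = rng.uniform(0.1, 1.0, mask.shape)
        f1 = photometric_features(make_object(mask, od))
        f2 = photometric_features(make_object(mask, 2 * od))
        assert f2["iod"] == pytest.approx(2 * f1["iod"])
        assert f2["od_mean"] == pytest.approx(2 * f1["od_mean"])
        assert f2["od_var"] == pytest.approx(4 * f1["od_var"])

    def test_moments_match_loop_oracle(self, rng):
        obj = random_object(rng)
        feats = photometric_features(obj)
        expected = moments_loop(list(obj.od_patch[obj.mask]))
        for k, v in expected.items():
            assert feats[k] == pytest.approx(v, abs=1e-9)

    def test_iod_additive_over_disjoint_masks(self, rng):
        od = rng.uniform(0.1, 1.0, (20, 40))
        left = np.zeros((20, 40), bool)
        left[5:15, 5:15] = True
        right = np.zeros((20, 40), bool)
        right[5:15, 25:35] = True
        iod = lambda m: photometric_features(make_object(m, od))["iod"]
        union_sum = od[left | right].sum()
        assert iod(left) + iod(right) == pytest.approx(union_sum, abs=1e-12)


class TestDiscreteTexture:
    def test_uniform_is_all_medium(self):
        obj = make_object(disk_mask(6))
        feats = discrete_texture_features(obj)
        assert feats["dt_med_area_frac"] == 1.0
        assert feats["dt_low_area_frac"] == 0.0
        assert feats["dt_high_area_frac"] == 0.0

    def test_two_level_split(self):
        mask = np.zeros((10, 20), bool)
        mask[2:8, 2:18] = True
        od = np.where(np.arange(20) < 10, 0.2, 1.0) * np.ones((10, 1))
        feats = discrete_texture_features(make_object(mask, od), thresholds=(0.75, 1.25))
        assert feats["dt_low_area_frac"] == pytest.approx(0.5)
        assert feats["dt_high_area_frac"] == pytest.approx(0.5)
        assert feats["dt_med_area_frac"] == 0.0

    def test_fractions_match_oracle(self, rng):
        obj = random_object(rng, size=14)
        feats = discrete_texture_features(obj)
        expected = dt_fractions_loop(obj.od_patch, obj.mask, (0.75, 1.25))
        for k, v in expected.items():
            assert feats[k] == pytest.approx(v, abs=1e-12)


class TestCooccurrence:
    def test_constant_patch(self):
        feats = cooccurrence_features(make_object(disk_mask(5)), q=8)
        assert feats["glcm_entropy"] == 0.0
        assert feats["glcm_energy"] == 1.0
        assert feats["glcm_contrast"] == 0.0

    def test_checkerboard_contrast_one(self):
        mask = np.ones((8, 8), bool)
        od = np.indices((8, 8)).sum(axis=0) % 2 * 1.0 + 0.1
        feats = cooccurrence_features(make_object(mask, od), q=2)
        assert feats["glcm_contrast"] == pytest.approx(1.0, abs=1e-12)

    def test_single_pixel_rejected(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        obj = NuclearObject(mask=mask, od_patch=np.where(mask, 0.5, 0.0),
                            contour=np.zeros((4, 2)), centroid=(1, 1), pixel_size=1.0)
        with pytest.raises(ValueError):
            cooccurrence_features(obj, q=4)

    def test_stats_match_pair_enumeration_oracle(self, rng):
        obj = random_object(rng, size=8)
        q = 6
        feats = cooccurrence_features(obj, q=q)
        expected = glcm_stats_loop(glcm_loop(quantize(obj, q), q))
        for k, v in expected.items():
            assert feats[k] == pytest.approx(v, abs=1e-9), k


class TestRunLength:
    def test_single_row_run_percentage(self):
        mask = np.zeros((3, 12), bool)
        mask[1, 1:11] = True  # one 10-px row
        obj = make_object(mask, np.full(mask.shape, 0.4))
        rlm = run_length_matrix(quantize(obj, 4), 4, (0, 1))
        n_runs = rlm.sum()
        assert n_runs == 1.0
        assert n_runs / obj.mask.sum() == pytest.approx(1 / 10)

    def test_alternating_row_short_run_emphasis(self):
        mask = np.zeros((3, 12), bool)
        mask[1, 1:11] = True
        od = np.tile(np.arange(12) % 2 * 1.0 + 0.1, (3, 1))
        feats = runlength_features(make_object(mask, od), q=2)
        assert feats["rl_sre"] == pytest.approx(1.0, abs=1e-12)

    def test_stats_match_run_enumeration_oracle(self, rng):
        obj = random_object(rng, size=10)
        q = 5
        quantized = quantize(obj, q)
        mats = [rlm_loop(quantized, q, d) for d in RL_DIRECTIONS]
        expected = rl_stats_loop(np.mean(mats, axis=0), int(obj.mask.sum()))
        feats = runlength_features(obj, q=q)
        for k, v in expected.items():
            assert feats[k] == pytest.approx(v, abs=1e-9), k


class TestFractalRadial:
    def test_flat_surface_dimension_two(self):
        mask = np.ones((40, 40), bool)
        feats = fractal_and_radial_features(make_object(mask, np.full((40, 40), 0.5)))
        assert feats["fractal_dim"] == pytest.approx(2.0, abs=0.1)

    def test_symmetric_patch_zero_displacement(self):
        mask = disk_mask(12)
        feats = fractal_and_radial_features(make_object(mask))
        assert feats["com_displacement"] == pytest.approx(0.0, abs=1e-6)

    def test_central_iod_concentration(self):
        mask = disk_mask(15)
        y, x = np.mgrid[: mask.shape[0], : mask.shape[1]]
        c = mask.shape[0] // 2
        od = np.where(np.hypot(y - c, x - c) <= 5, 1.0, 1e-6)
        feats = fractal_and_radial_features(make_object(mask, od))
        assert feats["inner_iod_frac"] > 0.99

    def test_small_object_flagged_missing(self):
        obj = make_object(disk_mask(3))
        feats = fractal_and_radial_features(obj)
        assert np.isnan(feats["fractal_dim"])
        assert "too_small" in obj.flags


class TestComputeQnp:
    def test_vector_complete_and_ordered(self):
        reg = default_registry()
        vec = compute_qnp(make_object(disk_mask(12)), reg)
        assert list(vec) == reg.names
        assert len(vec) == reg.feature_count

    def test_rotation_invariance(self, rng):
        mask = disk_mask(10)
        od = rng.uniform(0.1, 1.0, mask.shape)
        obj = make_object(mask, od)
        rot = make_object(np.rot90(mask).copy(), np.rot90(od).copy())
        v1, v2 = compute_qnp(obj), compute_qnp(rot)
        for name in ("glcm_entropy", "glcm_contrast", "rl_sre", "rl_rp"):
            assert v1[name] == pytest.approx(v2[name], abs=1e-6)
        assert v1["area_um2"] == pytest.approx(v2["area_um2"], rel=0.01)

    def test_physical_scale_invariance(self):
        """Upsampling 2x with half the pixel size preserves area in um^2."""
        mask = disk_mask(10)
        od = np.full(mask.shape, 0.5)
        v1 = compute_qnp(make_object(mask, od, pixel_size=0.5))
        big = np.kron(mask, np.ones((2, 2), bool))
        v2 = compute_qnp(make_object(big, np.full(big.shape, 0.5), pixel_size=0.25))
        assert v2["area_um2"] == pytest.approx(v1["area_um2"], rel=0.02)

    def test_oracle_equivalence_property(self):
        """All texture/photometric statistics match brute force on 100 random
        small patches."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            size = int(rng.integers(8, 17))
            obj = random_object(rng, size=size)
            q = int(rng.integers(2, 9))
            quantized = quantize(obj, q)

            ph = photometric_features(obj)
            for k, v in moments_loop(list(obj.od_patch[obj.mask])).items():
                assert ph[k] == pytest.approx(v, abs=1e-9), (seed, k)

            co = cooccurrence_features(obj, q=q)
            for k, v in glcm_stats_loop(glcm_loop(quantized, q)).items():
                assert co[k] == pytest.approx(v, abs=1e-9), (seed, k)

            rl = runlength_features(obj, q=q)
            mats = [rlm_loop(quantized, q, d) for d in RL_DIRECTIONS]
            for k, v in rl_stats_loop(np.mean(mats, axis=0), int(obj.mask.sum())).items():
                assert rl[k] == pytest.approx(v, abs=1e-9), (seed, k)

            dt = discrete_texture_features(obj)
            for k, v in dt_fractions_loop(obj.od_patch, obj.mask, (0.75, 1.25)).items():
                assert dt[k] == pytest.approx(v, abs=1e-12), (seed, k)

    def test_features_finite_on_extracted_objects(self, roi_image_fixture):
        """Every feature computed on real extracted objects is finite unless
        flagged too-small."""
        reg = default_registry()
        for obj in roi_image_fixture["objects"]:
            vec = compute_qnp(obj, reg)
            for name, v in vec.items():
                if "too_small" in obj.flags and not np.isfinite(v):
                    continue
                assert np.isfinite(v), (obj.object_id, name)
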