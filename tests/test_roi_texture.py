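"""Texture feature extraction: plane selection, quantization, matrix
builders against brute-force enumeration, and the frozen 32-name contract."""

import numpy as np
import pytest

from aeftex.roi_texture import (
    FEATURE_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    ROIMask,
    TextureConfig,
    extract_features,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    intensity_features,
    largest_axial_plane,
    quantize,
    tumor_area,
)

from _oracles import (
    brute_glcm,
    brute_glcm_features,
    brute_glrlm,
    brute_glrlm_features,
)
from conftest import aef_from_plane, roi_from_plane


class TestPlaneAndArea:
    def test_single_occupied_plane(self):
        mask = np.zeros((8, 6, 6), dtype=bool)
        mask[5, 2:4, 2:4] = True
        assert largest_axial_plane(ROIMask(mask=mask)) == 5

    def test_digital_sphere_peaks_at_center_plane(self):
        zz, yy, xx = np.ogrid[:9, :17, :17]
        mask = (zz - 4) ** 2 + (yy - 8) ** 2 + (xx - 8) ** 2 <= 36
        counts = [int(mask[k].sum()) for k in range(9)]  # brute-force per plane
        assert largest_axial_plane(ROIMask(mask=mask)) == int(np.argmax(counts)) == 4

    def test_tie_breaks_to_lower_index(self):
        mask = np.zeros((8, 6, 6), dtype=bool)
        mask[2, :3, :3] = True
        mask[6, 1:4, 1:4] = True
        assert largest_axial_plane(ROIMask(mask=mask)) == 2

    @pytest.mark.parametrize(
        "count, pixel_mm, expected",
        [(100, 0.8, 0.64), (1, 1.0, 0.01), (64 * 64, 0.8, 26.2144)],
    )
    def test_tumor_area(self, count, pixel_mm, expected):
        side = int(np.ceil(np.sqrt(count)))
        mask = np.zeros((3, max(side, 8), max(side, 8)), dtype=bool)
        mask[1].flat[:count] = True
        roi = ROIMask(mask=mask, voxel_size=(3.0, pixel_mm, pixel_mm))
        assert tumor_area(roi, 1) == pytest.approx(expected)

    def test_empty_plane_errors(self):
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[1, 2, 2] = True
        with pytest.raises(ValueError):
            tumor_area(ROIMask(mask=mask), 0)


class TestQuantize:
    def test_constant_maps_to_level_one(self):
        np.testing.assert_array_equal(quantize(np.full(9, 0.7), 8), np.ones(9, dtype=int))

    def test_endpoints(self):
        np.testing.assert_array_equal(quantize(np.array([0.0, 1.0]), 2), [1, 2])

    def test_uniform_grid_uses_each_level_once(self):
        values = np.linspace(0, 1, 64)
        levels = quantize(values, 64)
        counts = np.bincount(levels, minlength=65)[1:]
        assert (counts == 1).all()

    def test_levels_within_range(self, rng):
        levels = quantize(rng.normal(size=500), 16)
        assert levels.min() >= 1 and levels.max() == 16


class TestIntensityFeatures:
    CFG = TextureConfig(n_hist_bins=2, n_gray_levels=2)

    def test_constant_roi_degenerate(self):
        f = intensity_features(np.full(25, 0.7), TextureConfig())
        assert f["MinIntensity"] == f["MaxIntensity"] == 0.7
        assert f["MeanValue"] == pytest.approx(0.7)
        assert f["Variance"] == f["Range"] == f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == f["Kurtosis"] == 0.0

    def test_two_bin_entropy_and_uniformity(self):
        f = intensity_features(np.array([1.0, 1.0, 2.0, 2.0]), self.CFG)
        assert f["Entropy"] == pytest.approx(1.0)
        assert f["Uniformity"] == pytest.approx(0.5)
        assert f["Energy"] == pytest.approx(0.5)

    def test_symmetric_sample_zero_skewness(self, rng):
        x = rng.normal(size=101)
        x = np.concatenate([x, -x])  # exactly symmetric about 0
        f = intensity_features(x, TextureConfig())
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_moment_identities(self, rng):
        x = rng.lognormal(size=200)
        f = intensity_features(x, TextureConfig())
        assert f["Variance"] == pytest.approx(f["StdDeviation"] ** 2)
        assert f["Range"] == pytest.approx(f["MaxIntensity"] - f["MinIntensity"])
        assert f["RelativeDeviation"] == pytest.approx(f["StdDeviation"] / f["MeanValue"])
        assert f["VoxelValueSum"] == pytest.approx(x.sum())
        assert f["VolumeCount"] == x.size


class TestGLCM:
    def test_hand_counted_two_by_two(self):
        cfg = TextureConfig(n_gray_levels=2, directions=((0, 1),))
        levels = np.array([[1, 1], [1, 2]])
        roi = np.ones((2, 2), dtype=bool)
        (m,) = glcm(levels, roi, cfg)
        # two horizontal pairs (1,1) and (1,2); symmetrized
        assert m.p[0, 0] == pytest.approx(0.5)
        assert m.p[0, 1] == m.p[1, 0] == pytest.approx(0.25)

    def test_probability_conservation_and_symmetry(self, rng):
        cfg = TextureConfig(n_gray_levels=4)
        levels = rng.integers(1, 5, (7, 7))
        roi = rng.random((7, 7)) > 0.3
        roi[0, 0] = True
        for m in glcm(levels, roi, cfg):
            assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(m.p, m.p.T, atol=1e-15)

    def test_constant_plane_features(self):
        cfg = TextureConfig(n_gray_levels=4)
        levels = np.ones((5, 5), dtype=int)
        feats = glcm_features(glcm(levels, np.ones((5, 5), bool), cfg))
        assert feats["Inertia"] == 0.0
        assert feats["InverseDifferenceMoment"] == 1.0
        assert feats["Correlation"] == 1.0
        assert feats["HaralickCorrelation"] == 1.0

    def test_checkerboard_inertia_one(self):
        cfg = TextureConfig(n_gray_levels=2, directions=((0, 1),))
        levels = 1 + (np.indices((6, 6)).sum(axis=0) % 2)
        feats = glcm_features(glcm(levels, np.ones((6, 6), bool), cfg))
        assert feats["Inertia"] == pytest.approx(1.0)

    def test_no_pairs_raises(self):
        cfg = TextureConfig(n_gray_levels=2)
        roi = np.zeros((5, 5), dtype=bool)
        roi[0, 0] = True
        roi[3, 3] = False
        roi[0, 3] = True  # two isolated pixels, no unit-distance pair
        with pytest.raises(ValueError, match="no valid co-occurrence"):
            glcm(np.ones((5, 5), dtype=int), roi, cfg)


class TestGLRLM:
    CFG = TextureConfig(n_gray_levels=3, directions=((0, 1),))

    def test_hand_counted_row(self):
        levels = np.array([[1, 1, 2]])
        (m,) = glrlm(levels, np.ones((1, 3), bool), self.CFG)
        assert m.r[0, 1] == 1  # level 1, length 2
        assert m.r[1, 0] == 1  # level 2, length 1
        assert m.n_runs == 2

    def test_constant_row_single_run(self):
        levels = np.full((1, 7), 2)
        (m,) = glrlm(levels, np.ones((1, 7), bool), self.CFG)
        assert m.r[1, 6] == 1 and m.n_runs == 1

    def test_out_of_roi_breaks_runs(self):
        levels = np.array([[1, 1, 1, 1, 1]])
        roi = np.array([[True, True, False, True, True]])
        (m,) = glrlm(levels, roi, self.CFG)
        assert m.r[0, 1] == 2  # two runs of length 2

    def test_pixel_conservation_per_direction(self, rng):
        cfg = TextureConfig(n_gray_levels=4)
        levels = rng.integers(1, 5, (8, 8))
        roi = rng.random((8, 8)) > 0.35
        roi[0, 0] = True
        for m in glrlm(levels, roi, cfg):
            lengths = np.arange(1, m.r.shape[1] + 1)
            assert int((m.r * lengths).sum()) == int(roi.sum())

    def test_all_unit_runs_emphases(self, rng):
        cfg = TextureConfig(n_gray_levels=2, directions=((0, 1),))
        levels = 1 + (np.indices((4, 6)).sum(axis=0) % 2)  # checkerboard
        feats = glrlm_features(glrlm(levels, np.ones((4, 6), bool), cfg))
        assert feats["ShortRunEmphasis"] == 1.0
        assert feats["LongRunEmphasis"] == 1.0

    def test_single_run_of_length_four(self):
        cfg = TextureConfig(n_gray_levels=2, directions=((0, 1),))
        levels = np.full((1, 4), 1)
        feats = glrlm_features(glrlm(levels, np.ones((1, 4), bool), cfg))
        assert feats["ShortRunEmphasis"] == pytest.approx(1 / 16)
        assert feats["LongRunEmphasis"] == pytest.approx(16)

    def test_constant_plane_high_grey_emphasis_is_level_squared(self):
        cfg = TextureConfig(n_gray_levels=5, directions=((0, 1),))
        g = 5
        levels = np.full((1, 6), g)
        feats = glrlm_features(glrlm(levels, np.ones((1, 6), bool), cfg))
        assert feats["HighGreyLevelRunEmphasis"] == pytest.approx(g * g)


class TestOracleEquivalence:
    """Matrix builders and all 16 matrix features against independent
    brute-force enumeration on random small planes."""

    @pytest.mark.parametrize("ng", [2, 3, 4])
    def test_random_planes_match_brute_force(self, ng, rng):
        cfg = TextureConfig(n_gray_levels=ng)
        for _ in range(30):
            levels = rng.integers(1, ng + 1, (6, 6))
            roi = rng.random((6, 6)) > 0.25
            if not roi.any():
                roi[2, 2] = True
            # GLCM
            try:
                mats = glcm(levels, roi, cfg)
            except ValueError:
                mats = None
            ref = {
                d: brute_glcm(levels, roi, d, ng=ng)
                for d in cfg.directions
                if brute_glcm(levels, roi, d, ng=ng) is not None
            }
            if mats is None:
                assert not ref
            else:
                assert {m.direction for m in mats} == set(ref)
                for m in mats:
                    np.testing.assert_allclose(m.p, ref[m.direction], atol=1e-10)
                ours = glcm_features(mats)
                refs = [brute_glcm_features(ref[m.direction]) for m in mats]
                for name in ours:
                    expected = np.mean([r[name] for r in refs])
                    np.testing.assert_allclose(ours[name], expected, atol=1e-10,
                                               rtol=1e-10, err_msg=name)
            # GLRLM
            rmats = glrlm(levels, roi, cfg)
            for m in rmats:
                np.testing.assert_array_equal(
                    m.r, brute_glrlm(levels, roi, m.direction, ng=ng, lmax=m.r.shape[1])
                )
            ours = glrlm_features(rmats)
            refs = [
                brute_glrlm_features(m.r) for m in rmats if m.n_runs > 0
            ]
            for name in ours:
                expected = np.mean([r[name] for r in refs])
                np.testing.assert_allclose(ours[name], expected, atol=1e-10,
                                           rtol=1e-10, err_msg=name)


class TestExtractFeatures:
    def test_exactly_32_frozen_names(self, rng):
        vals = rng.uniform(0.2, 1.8, (9, 9))
        fv = extract_features(aef_from_plane(vals), roi_from_plane(np.ones((9, 9), bool)))
        assert tuple(fv.values) == FEATURE_NAMES
        assert len(fv.values) == 32
        assert np.isfinite(fv.as_array()).all()

    def test_shuffle_invariance_of_intensity_but_not_matrix_features(self, rng):
        vals = rng.uniform(0.2, 1.8, (12, 12))
        roi = np.ones((12, 12), bool)
        fv1 = extract_features(aef_from_plane(vals), roi_from_plane(roi))
        shuffled = vals.copy().ravel()
        rng.shuffle(shuffled)
        fv2 = extract_features(aef_from_plane(shuffled.reshape(12, 12)), roi_from_plane(roi))
        for name in ("MinIntensity", "MaxIntensity", "MeanValue", "Variance",
                     "Skewness", "Kurtosis", "Entropy", "Uniformity", "Energy"):
            assert fv1[name] == pytest.approx(fv2[name], rel=1e-12), name
        assert any(
            abs(fv1[n] - fv2[n]) > 1e-9 for n in ("Inertia", "InverseDifferenceMoment",
                                                  "ShortRunEmphasis", "LongRunEmphasis")
        )

    def test_heterogeneity_lowers_energy_raises_entropy(self, rng):
        """Across replicates, a half-arterialized fine-grained lesion has
        lower Energy and higher Entropy than a nearly homogeneous one."""
        from aeftex.aef import compute_aef_map
        from aeftex.synthetic_data import LesionSpec, PhantomSpec, generate_multiphase_phantom

        def feat(frac, scale, seed):
            spec = PhantomSpec(
                grid_shape=(10, 40, 40),
                lesions=(LesionSpec(center=(5, 20, 20), radius=10,
                                    arterialized_fraction=frac, cluster_scale=scale),),
                noise_sd=4.0,
                seed=seed,
            )
            mv, roi = generate_multiphase_phantom(spec)
            return extract_features(compute_aef_map(mv), ROIMask(mask=roi))

        wins_energy = wins_entropy = 0
        n_rep = 25
        for rep in range(n_rep):
            homo = feat(0.05, 2.5, 100 + rep)
            hetero = feat(0.5, 1.2, 100 + rep)
            wins_energy += hetero["Energy"] < homo["Energy"]
            wins_entropy += hetero["Entropy"] > homo["Entropy"]
        assert wins_energy >= int(0.95 * n_rep)
        assert wins_entropy >= int(0.95 * n_rep)

    def test_mask_shape_mismatch_raises(self, rng):
        fv_aef = aef_from_plane(rng.uniform(size=(6, 6)))
        with pytest.raises(ValueError, match="shape"):
            extract_features(fv_aef, roi_from_plane(np.ones((7, 7), bool)))

    def test_no_valid_voxels_raises(self):
        aef = aef_from_plane(np.ones((6, 6)))
        object.__setattr__(aef, "valid", np.zeros_like(aef.valid))
        with pytest.raises(ValueError, match="no valid AEF voxels"):
            extract_features(aef, roi_from_plane(np.ones((6, 6), bool)))
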