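"""Handcrafted texture and shape features against hand computations and
brute-force counting oracles."""

import numpy as np
import pandas as pd
import pytest

from sarcomics.images import SegmentationMask
from sarcomics.radiomics import (DIRECTIONS_13, extract_features,
                                 filter_robust_features, first_order_features,
                                 glcm_features, glrlm_features, glzlm_features,
                                 icc, ngldm_features, shape_features)

from oracles import brute_glcm, brute_glcm_stats, brute_runs

FULL = np.ones((4, 4, 1), bool)


# ------------------------------------------------------------- first order

class TestFirstOrder:
    def test_constant_region(self):
        f = first_order_features(np.full((4, 4, 1), 3), FULL)
        assert f["fo_variance"] == 0
        assert f["fo_entropy"] == 0
        assert f["fo_energy"] == 1
        assert f["fo_occupied_levels"] == 1

    def test_two_level_entropy_hand_value(self):
        d = np.array([1, 1, 1, 2]).reshape(4, 1, 1)
        f = first_order_features(d, np.ones((4, 1, 1), bool))
        expect = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert f["fo_entropy"] == pytest.approx(expect, abs=1e-4)
        assert f["fo_energy"] == pytest.approx(0.75 ** 2 + 0.25 ** 2)

    def test_symmetric_two_point_skewness_zero(self):
        d = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
        f = first_order_features(d, np.ones((4, 1, 1), bool))
        assert f["fo_skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_count_is_thirteen(self):
        f = first_order_features(np.full((2, 2, 2), 2), np.ones((2, 2, 2), bool))
        assert len(f) == 13


# -------------------------------------------------------------------- GLCM

class TestGLCM:
    def test_checkerboard_matches_oracle(self):
        d = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        mine = glcm_features(d, FULL, distances=(1,))
        P = brute_glcm(d, FULL, 1)
        ref = brute_glcm_stats(P)
        for name, val in ref.items():
            assert mine[f"glcm_{name}_d1"] == pytest.approx(val, abs=1e-12), name

    def test_constant_region_neutral(self):
        f = glcm_features(np.full((4, 4, 1), 5), FULL)
        for d in (1, 2):
            assert f[f"glcm_contrast_d{d}"] == 0
            assert f[f"glcm_energy_d{d}"] == 1
            assert f[f"glcm_entropy_d{d}"] == 0

    def test_linear_gradient_correlation_matches_pair_pearson(self):
        # perfect gradient along one direction: correlation equals the
        # Pearson correlation over the symmetrized pair multiset
        d = np.tile(np.arange(1, 9)[:, None, None], (1, 1, 1))
        mask = np.ones((8, 1, 1), bool)
        f = glcm_features(d, mask, distances=(1,), directions=[(1, 0, 0)])
        pairs = [(i, i + 1) for i in range(1, 8)]
        pairs += [(j, i) for i, j in pairs]
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)
        expect = np.corrcoef(x, y)[0, 1]
        assert f["glcm_correlation_d1"] == pytest.approx(expect, abs=1e-12)
        assert f["glcm_correlation_d1"] > 0.85

    def test_count_is_21(self):
        d = np.indices((4, 4, 2)).sum(axis=0) % 3 + 1
        f = glcm_features(d, np.ones((4, 4, 2), bool))
        assert len(f) == 21


# ------------------------------------------------------------------- GLRLM

class TestGLRLM:
    def test_single_row_hand_enumeration(self):
        d = np.array([1, 1, 1, 2]).reshape(4, 1, 1)
        m = np.ones((4, 1, 1), bool)
        f = glrlm_features(d, m, directions=[(1, 0, 0)])
        # runs {(1, len 3), (2, len 1)}
        assert f["glrlm_rp"] == pytest.approx(0.5)
        assert f["glrlm_lre"] == pytest.approx((9 + 1) / 2)
        assert f["glrlm_sre"] == pytest.approx((1 / 9 + 1) / 2)

    def test_constant_line_closed_form(self):
        n = 7
        d = np.full((n, 1, 1), 4)
        f = glrlm_features(d, np.ones((n, 1, 1), bool), directions=[(1, 0, 0)])
        assert f["glrlm_lre"] == pytest.approx(n ** 2)
        assert f["glrlm_rp"] == pytest.approx(1.0 / n)

    def test_all_runs_length_one(self):
        d = np.arange(1, 9).reshape(8, 1, 1)
        f = glrlm_features(d, np.ones((8, 1, 1), bool), directions=[(1, 0, 0)])
        assert f["glrlm_sre"] == pytest.approx(1.0)
        assert f["glrlm_rp"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_volume_matches_walking_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(1, 4, size=(4, 3, 3))
        m = rng.uniform(size=(4, 3, 3)) > 0.3
        if not m.any():
            pytest.skip("empty mask draw")
        mine = glrlm_features(d, m)
        runs = brute_runs(np.where(m, d, 0), m, DIRECTIONS_13)
        g = np.array([r[0] for r in runs], float)
        l = np.array([r[1] for r in runs], float)
        n_r = len(runs)
        assert mine["glrlm_rp"] == pytest.approx(n_r / (m.sum() * 13))
        assert mine["glrlm_sre"] == pytest.approx(np.mean(1 / l ** 2))
        assert mine["glrlm_lre"] == pytest.approx(np.mean(l ** 2))
        assert mine["glrlm_hgre"] == pytest.approx(np.mean(g ** 2))


# ------------------------------------------------------------------- NGLDM

class TestNGLDM:
    def test_constant_region_contrast_zero_coarseness_capped(self):
        f = ngldm_features(np.full((4, 4, 2), 3), np.ones((4, 4, 2), bool))
        assert f["ngldm_contrast"] == 0
        assert f["ngldm_coarseness"] == 1e6

    def test_alternating_strip_matches_neighborhood_oracle(self):
        d = np.array([1, 2, 1, 2, 1, 2]).reshape(6, 1, 1)
        m = np.ones((6, 1, 1), bool)
        f = ngldm_features(d, m)
        # manual s_i: every voxel's neighbors all have the other level
        s = {}
        for i in range(6):
            nb = [d[j, 0, 0] for j in (i - 1, i + 1) if 0 <= j < 6]
            s.setdefault(d[i, 0, 0], 0.0)
            s[d[i, 0, 0]] += abs(d[i, 0, 0] - np.mean(nb))
        p = {1: 0.5, 2: 0.5}
        coarse = 1.0 / sum(p[g] * s[g] for g in (1, 2))
        ng, n = 2, 6
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in (1, 2) for j in (1, 2))
                    / (ng * (ng - 1))) * (sum(s.values()) / n)
        assert f["ngldm_coarseness"] == pytest.approx(coarse)
        assert f["ngldm_contrast"] == pytest.approx(contrast)


# ------------------------------------------------------------------- GLZLM

class TestGLZLM:
    def test_single_zone(self):
        f = glzlm_features(np.full((3, 3, 1), 2), np.ones((3, 3, 1), bool))
        assert f["glzlm_rp"] == pytest.approx(1.0 / 9)
        assert f["glzlm_lre"] == pytest.approx(81.0)

    def test_isolated_single_voxel_zones(self):
        d = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        # 4-connectivity would merge diagonals; use separated voxels
        m = np.zeros((4, 4, 1), bool)
        m[0, 0] = m[0, 3] = m[3, 0] = m[3, 3] = True
        f = glzlm_features(d, m)
        assert f["glzlm_rp"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_zone_count_matches_flood_fill(self, seed):
        from scipy import ndimage
        rng = np.random.default_rng(seed)
        d = rng.integers(1, 3, size=(5, 5, 3))
        m = rng.uniform(size=(5, 5, 3)) > 0.3
        if not m.any():
            pytest.skip("empty mask draw")
        f = glzlm_features(d, m)
        n_zones = 0
        for g in np.unique(d[m]):
            _, n = ndimage.label(m & (d == g), structure=np.ones((3, 3, 3)))
            n_zones += n
        assert f["glzlm_rp"] == pytest.approx(n_zones / m.sum())


# ------------------------------------------------------------------- shape

class TestShape:
    def test_single_voxel_volume(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        f = shape_features(SegmentationMask(m, (1, 1, 4)))
        assert f["shape_volume_ml"] == pytest.approx(0.004)
        assert f["shape_voxel_count"] == 1

    def test_cube_voxel_count_and_internal_consistency(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        f = shape_features(SegmentationMask(m, (1, 1, 1)))
        assert f["shape_voxel_count"] == 27
        # sphericity and compacity must agree on the same surface area
        v = f["shape_volume_ml"] * 1000
        area_from_sph = np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / f["shape_sphericity"]
        assert f["shape_compacity"] == pytest.approx(area_from_sph / v)

    def test_large_ball_sphericity_approaches_one(self):
        n = 45
        c = (n - 1) / 2
        ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        m = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= 20 ** 2
        f = shape_features(SegmentationMask(m, (1, 1, 1)))
        assert 0.9 <= f["shape_sphericity"] <= 1.0


# -------------------------------------------------------- assembly and ICC

class TestAssembly:
    def test_feature_count_59_per_sequence_plus_4_shape(self, small_study):
        from sarcomics.harmonize import discretize, harmonize_volume
        disc = {}
        for name, vol in small_study.channels.items():
            h, m = harmonize_volume(vol, small_study.mask)
            disc[name] = discretize(h, m)
        feats = extract_features(disc, m, spacing=m.spacing)
        assert len(feats) == 59 * 3 + 4
        assert all(np.isfinite(v) for v in feats.values())

    @pytest.mark.parametrize("trial", range(5))
    def test_texture_invariant_to_affine_intensity(self, trial):
        from sarcomics.harmonize import discretize
        from sarcomics.images import ImageVolume
        rng = np.random.default_rng(trial)
        v = rng.normal(0, 1, (6, 6, 4))
        m = SegmentationMask(rng.uniform(size=(6, 6, 4)) > 0.3)
        a, b = rng.uniform(0.5, 3), rng.normal(0, 10)
        d1 = discretize(ImageVolume(v), m)
        d2 = discretize(ImageVolume(a * v + b), m)
        f1 = extract_features({"X": d1}, m, shape_channel=None)
        f2 = extract_features({"X": d2}, m, shape_channel=None)
        assert f1 == f2


class TestICC:
    def test_identical_repeats_icc_one(self, rng):
        base = rng.normal(0, 1, (10, 1))
        x = np.stack([base, base], axis=1)
        assert icc(x).iloc[0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (200, 2, 1))
        assert abs(icc(x).iloc[0]) < 0.1

    def test_planted_variance_ratio(self):
        rng = np.random.default_rng(4)
        subj = rng.normal(0, 3.0, (500, 1, 1))
        x = subj + rng.normal(0, 1, (500, 2, 1))
        assert icc(x).iloc[0] == pytest.approx(0.9, abs=0.05)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (30, 2, 1)) + rng.normal(0, 2, (30, 1, 1))
        mine = icc(x).iloc[0]
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(30), 2),
            "rater": np.tile([0, 1], 30),
            "y": x[:, :, 0].ravel(),
        })
        res = pg.intraclass_corr(df, targets="subj", raters="rater",
                                 ratings="y").set_index("Type")
        key = "ICC2" if "ICC2" in res.index else "ICC(A,1)"
        ref = res.loc[key, "ICC"]
        assert mine == pytest.approx(ref, abs=1e-9)


class TestRobustFilter:
    def test_boundary_inclusive(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                           columns=["a", "b", "c"])
        report = pd.Series({"a": 0.95, "b": 0.90, "c": 0.89})
        kept = filter_robust_features(mat, report)
        assert list(kept.columns) == ["a", "b"]

    def test_threshold_zero_keeps_all(self):
        mat = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        report = pd.Series({"a": 0.1, "b": 0.2})
        assert filter_robust_features(mat, report, threshold=0).shape[1] == 2

    def test_none_surviving_raises(self):
        mat = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        report = pd.Series({"a": 0.5, "b": 0.5})
        with pytest.raises(ValueError):
            filter_robust_features(mat, report, threshold=1.01)
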