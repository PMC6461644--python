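"""Texture features against exhaustive pair/run enumeration."""

import numpy as np
import pytest

import oracles
from gbmprog.texture import (
    DIRECTIONS_3D,
    GLCM_FEATURES,
    RLM_FEATURES,
    compute_texture,
    glcm_features,
    glcm_matrix,
    gradient_features,
    quantize,
    rlm_features,
    rlm_matrix,
)


def oracle_glcm_features(counts):
    """Haralick statistics computed directly from a raw count matrix."""
    p = counts / counts.sum()
    g = p.shape[0]
    feats = {k: 0.0 for k in GLCM_FEATURES}
    mu_i = sum((i + 1) * p[i, j] for i in range(g) for j in range(g))
    mu_j = sum((j + 1) * p[i, j] for i in range(g) for j in range(g))
    sd_i = np.sqrt(sum((i + 1 - mu_i) ** 2 * p[i, j]
                       for i in range(g) for j in range(g)))
    sd_j = np.sqrt(sum((j + 1 - mu_j) ** 2 * p[i, j]
                       for i in range(g) for j in range(g)))
    psum, pdiff = {}, {}
    for i in range(g):
        for j in range(g):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    for i in range(g):
        for j in range(g):
            v = p[i, j]
            if v == 0:
                continue
            feats["cm_energy"] += v * v
            feats["cm_entropy"] -= v * np.log2(v)
            feats["cm_contrast"] += (i - j) ** 2 * v
            feats["cm_homogeneity"] += v / (1 + (i - j) ** 2)
            feats["cm_dissimilarity"] += abs(i - j) * v
            feats["cm_autocorrelation"] += (i + 1) * (j + 1) * v
            feats["cm_cluster_shade"] += (i + j + 2 - mu_i - mu_j) ** 3 * v
            feats["cm_cluster_prominence"] += (i + j + 2 - mu_i - mu_j) ** 4 * v
    feats["cm_sum_average"] = sum(k * v for k, v in psum.items())
    feats["cm_sum_entropy"] = -sum(v * np.log2(v) for v in psum.values() if v > 0)
    feats["cm_difference_entropy"] = -sum(
        v * np.log2(v) for v in pdiff.values() if v > 0)
    if sd_i * sd_j > 0:
        feats["cm_correlation"] = sum(
            (i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j]
            for i in range(g) for j in range(g)) / (sd_i * sd_j)
    else:
        feats["cm_correlation"] = 1.0
    return feats


def oracle_rlm_features(rlm, n_voxels):
    nr = rlm.sum()
    g, lmax = rlm.shape
    out = {k: 0.0 for k in RLM_FEATURES}
    for i in range(g):
        for j in range(lmax):
            v = rlm[i, j]
            lev, ln = i + 1, j + 1
            out["rlm_sre"] += v / ln**2
            out["rlm_lre"] += v * ln**2
            out["rlm_lgre"] += v / lev**2
            out["rlm_hgre"] += v * lev**2
            out["rlm_srlge"] += v / (lev**2 * ln**2)
            out["rlm_srhge"] += v * lev**2 / ln**2
            out["rlm_lrlge"] += v * ln**2 / lev**2
            out["rlm_lrhge"] += v * lev**2 * ln**2
    out["rlm_gln"] = sum(rlm[i, :].sum() ** 2 for i in range(g))
    out["rlm_rln"] = sum(rlm[:, j].sum() ** 2 for j in range(lmax))
    for k in out:
        out[k] /= nr
    out["rlm_rp"] = nr / n_voxels
    return out


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_glcm_counts_and_features_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 7, size=3))
        img = rng.integers(0, 30, size=shape).astype(float)
        mask = rng.uniform(size=shape) < 0.8
        mask.flat[0] = True
        img.flat[0] = 0.0; img.flat[-1] = 29.0  # span the range
        levels = 4
        q = quantize(img, mask, levels)
        for off in DIRECTIONS_3D:
            counts = oracles.glcm_pairs_brute(q.quantized, off, levels)
            p = glcm_matrix(q, off)
            if counts.sum() == 0:
                assert p.sum() == 0
                continue
            # counts are integers; undo the normalization before comparing
            assert np.array_equal(np.round(p * counts.sum()), counts)
            assert np.allclose(p * counts.sum(), counts, atol=1e-9)
            ours = glcm_features(p)
            theirs = oracle_glcm_features(counts)
            for k in GLCM_FEATURES:
                assert ours[k] == pytest.approx(theirs[k], abs=1e-9), k

    @pytest.mark.parametrize("seed", range(4))
    def test_rlm_matrix_and_features_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        shape = tuple(rng.integers(3, 7, size=3))
        img = rng.integers(0, 6, size=shape).astype(float)
        mask = rng.uniform(size=shape) < 0.85
        mask.flat[:2] = True
        img.flat[0] = 0.0; img.flat[1] = 5.0
        levels = 3
        q = quantize(img, mask, levels)
        n_voxels = int(mask.sum())
        for off in DIRECTIONS_3D:
            brute = oracles.rlm_runs_brute(q.quantized, off, levels)
            ours = rlm_matrix(q, off)
            width = max(brute.shape[1], ours.shape[1])
            b = np.zeros((levels, width)); b[:, :brute.shape[1]] = brute
            o = np.zeros((levels, width)); o[:, :ours.shape[1]] = ours
            assert np.array_equal(b, o)
            f_ours = rlm_features(ours, n_voxels)
            f_theirs = oracle_rlm_features(b, n_voxels)
            for k in RLM_FEATURES:
                assert f_ours[k] == pytest.approx(f_theirs[k], abs=1e-9), k


class TestDegenerateAndToyCases:
    def test_constant_image_degenerates_cleanly(self):
        img = np.full((4, 4, 4), 7.0)
        mask = np.ones((4, 4, 4), bool)
        feats = compute_texture(img, mask, levels=8)
        assert feats["cm_energy"] == pytest.approx(1.0)
        assert feats["cm_entropy"] == pytest.approx(0.0)
        assert feats["gradient_mean"] == 0.0
        assert feats["gradient_nonzero_fraction"] == 0.0
        assert feats["rlm_lgre"] == pytest.approx(1.0)  # single level 1

    def test_checkerboard_in_plane_hand_values(self):
        # 4x4x1 two-level checkerboard: along axis offsets every neighbour
        # differs, so all runs have length 1 and CM contrast is 1
        img = np.indices((1, 4, 4)).sum(axis=0) % 2
        mask = np.ones((1, 4, 4), bool)
        q = quantize(img.astype(float), mask, 2)
        for off in ((0, 0, 1), (0, 1, 0)):
            p = glcm_matrix(q, off)
            assert glcm_features(p)["cm_contrast"] == pytest.approx(1.0)
            rlm = rlm_matrix(q, off)
            assert rlm.shape[1] == 1  # no run longer than 1
            assert rlm.sum() == 16
        # diagonal offset connects equal cells: all runs along it merge
        p_diag = glcm_matrix(q, (0, 1, 1))
        assert glcm_features(p_diag)["cm_contrast"] == pytest.approx(0.0)

    def test_ramp_line_runs(self):
        img = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        mask = np.ones((1, 1, 4), bool)
        q = quantize(img, mask, 4)
        rlm = rlm_matrix(q, (0, 0, 1))
        assert rlm.shape == (4, 1)
        assert np.array_equal(rlm[:, 0], np.ones(4))
        feats = rlm_features(rlm, 4)
        assert feats["rlm_rp"] == pytest.approx(1.0)


class TestInvariants:
    def test_cm_probability_sums_to_one_per_direction(self):
        rng = np.random.default_rng(7)
        img = rng.normal(size=(5, 5, 5))
        mask = rng.uniform(size=(5, 5, 5)) < 0.7
        mask[2, 2, 2] = True
        img[mask][0:2] = [img[mask].min() - 1, img[mask].max() + 1]
        q = quantize(img, mask, 5)
        for off in DIRECTIONS_3D:
            p = glcm_matrix(q, off)
            if p.sum() > 0:
                assert p.sum() == pytest.approx(1.0)

    def test_affine_intensity_shift_invariance(self):
        rng = np.random.default_rng(11)
        img = rng.normal(size=(5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        f1 = compute_texture(img, mask, levels=6)
        f2 = compute_texture(3.0 * img + 10.0, mask, levels=6)
        for k in GLCM_FEATURES + RLM_FEATURES:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k

    def test_rlm_total_weighted_length_is_voxel_count(self):
        rng = np.random.default_rng(13)
        img = rng.integers(0, 4, size=(5, 4, 6)).astype(float)
        mask = rng.uniform(size=(5, 4, 6)) < 0.8
        mask.flat[:2] = True
        img.flat[0] = 0; img.flat[1] = 3
        q = quantize(img, mask, 4)
        n = int(mask.sum())
        for off in DIRECTIONS_3D:
            rlm = rlm_matrix(q, off)
            lengths = np.arange(1, rlm.shape[1] + 1)
            assert (rlm * lengths).sum() == n

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            compute_texture(np.zeros((3, 3, 3)), np.ones((4, 4, 4), bool))

    def test_gradient_spacing_scales_magnitude(self):
        img = np.tile(np.arange(8.0), (8, 8, 1))
        mask = np.ones((8, 8, 8), bool)
        g1 = gradient_features(img, mask, (1.0, 1.0, 1.0))
        g2 = gradient_features(img, mask, (1.0, 1.0, 2.0))
        assert g2["gradient_mean"] == pytest.approx(g1["gradient_mean"] / 2)
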