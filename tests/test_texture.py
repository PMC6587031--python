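"""Texture and shape features: hand-built matrix oracles, degenerate ROIs,
invariance properties and the static catalog arithmetic."""

import itertools

import numpy as np
import pytest
from skimage.feature import graycomatrix

from seqradiomics.extract import extract_static_features
from seqradiomics.manifest import TEXTURE_FEATURE_IDS
from seqradiomics.shape import compute_shape_features
from seqradiomics.texture import (OFFSETS_13, compute_texture_features,
                                  discretize, glcm_features, glcm_matrix,
                                  glrlm_matrix, glszm_matrix)
from seqradiomics.types import ImageVolume, TumorMask


def vol(arr, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(arr, dtype=float), spacing=spacing)


def mask(arr, spacing=(1.0, 1.0, 1.0)):
    return TumorMask(np.asarray(arr, dtype=bool), spacing=spacing)


def glcm_bruteforce(levels, roi, n_levels, offsets):
    """Independent co-occurrence oracle: explicit voxel-pair loops."""
    mats = []
    shape = levels.shape
    for d in offsets:
        counts = np.zeros((n_levels, n_levels))
        for idx in itertools.product(*(range(s) for s in shape)):
            if not roi[idx]:
                continue
            nb = tuple(i + di for i, di in zip(idx, d))
            if any(not (0 <= v < s) for v, s in zip(nb, shape)) or not roi[nb]:
                continue
            a, b = levels[idx] - 1, levels[nb] - 1
            counts[a, b] += 1
            counts[b, a] += 1
        if counts.sum():
            mats.append(counts / counts.sum())
    return np.mean(mats, axis=0)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_constant_roi_degenerate_limits(rng):
    v = vol(np.full((4, 4, 4), 7.0))
    m = mask(np.ones((4, 4, 4)))
    out = compute_texture_features(v, m)
    assert out["firstorder_variance"] == 0.0
    assert out["firstorder_entropy"] == 0.0
    assert out["glcm_contrast"] == 0.0
    assert out["glcm_correlation"] == 1.0


def test_checkerboard_glcm_axial_contrast_is_one():
    # two-level checkerboard: every axial neighbor pair differs by one level
    zz, yy, xx = np.indices((4, 4, 1))
    board = ((zz + yy + xx) % 2).astype(float)
    levels = discretize(board, 2)
    roi = np.ones((4, 4, 1), dtype=bool)
    P = glcm_matrix(levels, roi, 2, offsets=[(0, 0, 1), (0, 1, 0)][1:])
    feats = glcm_features(P, 2)
    assert np.diag(P).sum() == 0.0  # off-diagonal mass only
    assert feats["contrast"] == pytest.approx(1.0)


def test_glcm_matches_bruteforce_13_offsets(rng):
    arr = rng.integers(0, 4, size=(5, 5, 3)).astype(float)
    roi = rng.random((5, 5, 3)) > 0.3
    roi[2, 2, 1] = True  # keep nonempty
    levels = discretize(arr, 4)
    got = glcm_matrix(levels, roi, 4, OFFSETS_13)
    expected = glcm_bruteforce(levels, roi, 4, OFFSETS_13)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_glcm_matches_skimage_2d(rng):
    # single-slice volume, one horizontal offset: compare with
    # skimage.feature.graycomatrix (symmetric, normalized)
    img = rng.integers(0, 6, size=(8, 8)).astype(np.uint8)
    sk = graycomatrix(img, distances=[1], angles=[0.0], levels=6,
                      symmetric=True, normed=True)[:, :, 0, 0]
    levels3d = (img + 1).astype(np.int64)[:, :, None]
    roi = np.ones_like(levels3d, dtype=bool)
    ours = glcm_matrix(levels3d, roi, 6, offsets=[(0, 1, 0)])
    np.testing.assert_allclose(ours, sk, atol=1e-12)


def test_firstorder_entropy_uniform_eight_levels():
    # values 1..8 uniformly, 8 bins -> -sum (1/8) log2 (1/8) = 3 bits
    arr = np.tile(np.arange(1, 9, dtype=float), 8).reshape(8, 8, 1)
    out = compute_texture_features(vol(arr), mask(np.ones((8, 8, 1))),
                                   bin_count=8)
    assert out["firstorder_entropy"] == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# GLRLM / GLSZM oracles
# ---------------------------------------------------------------------------

def test_glrlm_runs_along_single_direction():
    arr = np.array([1, 1, 2, 2, 2, 1], dtype=float).reshape(1, 1, 6)
    levels = discretize(arr, 2)
    roi = np.ones_like(levels, dtype=bool)
    R = glrlm_matrix(levels, roi, 2, offsets=[(0, 0, 1)])
    # level 1: runs of length 2 and 1; level 2: one run of length 3
    assert R[0, 1] == 1.0 and R[0, 0] == 1.0
    assert R[1, 2] == 1.0
    assert R.sum() == 3.0


def test_glrlm_total_voxels_conserved(rng):
    arr = rng.integers(0, 3, size=(4, 4, 4)).astype(float)
    roi = rng.random((4, 4, 4)) > 0.4
    roi[0, 0, 0] = True
    levels = discretize(arr, 3)
    for d in [(0, 0, 1), (1, 1, 0), (1, 1, 1)]:
        R = glrlm_matrix(levels, roi, 3, offsets=[d])
        lengths = np.arange(1, R.shape[1] + 1)
        assert (R * lengths).sum() == pytest.approx(roi.sum())


def test_glszm_zone_sizes():
    arr = np.zeros((1, 1, 7))
    arr[0, 0, :3] = 5.0  # one 3-voxel zone of the high level
    arr[0, 0, 5] = 5.0   # one isolated high voxel
    levels = discretize(arr, 2)
    roi = np.ones_like(levels, dtype=bool)
    S = glszm_matrix(levels, roi, 2)
    assert S[1, 2] == 1.0 and S[1, 0] == 1.0  # sizes 3 and 1 for level 2
    assert S[0, 1] == 1.0 and S[0, 0] == 1.0  # background level zones: 2 and 1


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

def test_outside_mask_voxels_are_ignored(rng):
    arr = rng.random((6, 6, 6)) * 50
    roi = np.zeros((6, 6, 6), dtype=bool)
    roi[1:5, 1:5, 1:5] = True
    out1 = compute_texture_features(vol(arr), mask(roi))
    arr2 = arr.copy()
    arr2[~roi] = -999.0
    out2 = compute_texture_features(vol(arr2), mask(roi))
    for k in TEXTURE_FEATURE_IDS:
        assert out1[k] == pytest.approx(out2[k], rel=1e-12), k


def test_fixed_bin_count_affine_invariance(rng):
    arr = rng.random((6, 6, 6)) * 30 + 5
    roi = np.ones((6, 6, 6), dtype=bool)
    out1 = compute_texture_features(vol(arr), mask(roi))
    out2 = compute_texture_features(vol(arr * 4.2 + 17.0), mask(roi))
    discretized = [k for k in TEXTURE_FEATURE_IDS
                   if not k.startswith("firstorder")
                   or k in ("firstorder_entropy", "firstorder_uniformity")]
    for k in discretized:
        assert out1[k] == pytest.approx(out2[k], rel=1e-9), k


def test_single_voxel_roi_is_finite():
    roi = np.zeros((5, 5, 5), dtype=bool)
    roi[2, 2, 2] = True
    out = compute_texture_features(vol(np.ones((5, 5, 5))), mask(roi))
    assert all(np.isfinite(v) for v in out.values())


# ---------------------------------------------------------------------------
# shape features
# ---------------------------------------------------------------------------

def test_single_voxel_shape_bounds():
    roi = np.zeros((5, 5, 5), dtype=bool)
    roi[2, 2, 2] = True
    out = compute_shape_features(mask(roi))
    # the marching-cubes surface of one voxel is an octahedron (volume 1/6)
    assert 0.0 < out["mesh_volume"] <= 1.0
    assert out["maximum_3d_diameter"] <= np.sqrt(3.0)
    assert out["voxel_volume"] == 1.0


def test_digital_ball_sphericity():
    zz, yy, xx = np.indices((25, 25, 25)) - 12.0
    ball = zz ** 2 + yy ** 2 + xx ** 2 <= 10.0 ** 2
    out = compute_shape_features(mask(ball))
    assert 0.95 <= out["sphericity"] <= 1.0
    assert out["elongation"] == pytest.approx(1.0, abs=0.02)


def test_two_voxel_maximum_diameter():
    roi = np.zeros((3, 3, 12), dtype=bool)
    roi[1, 1, 0] = True
    roi[1, 1, 10] = True
    out = compute_shape_features(mask(roi))
    assert out["maximum_3d_diameter"] == pytest.approx(10.0)


def test_shape_scales_with_spacing():
    roi = np.zeros((8, 8, 8), dtype=bool)
    roi[2:6, 2:6, 2:6] = True
    iso = compute_shape_features(mask(roi, spacing=(1, 1, 1)))
    big = compute_shape_features(mask(roi, spacing=(2, 2, 2)))
    assert big["voxel_volume"] == pytest.approx(8 * iso["voxel_volume"])
    assert big["maximum_3d_diameter"] == pytest.approx(
        2 * iso["maximum_3d_diameter"])


# ---------------------------------------------------------------------------
# static catalog arithmetic
# ---------------------------------------------------------------------------

def test_static_catalog_counts(tiny_static_table):
    groups = [m.group for m in tiny_static_table.feature_meta]
    assert groups.count("DCE_shape") == 14
    assert groups.count("DCE_texture") == 552  # 92 x 6 phases
    assert groups.count("DWI_texture") == 276  # 92 x 3 b-values
    assert tiny_static_table.n_features == 842


def test_row_order_follows_cohort_order(tiny_cohort):
    t1 = extract_static_features(tiny_cohort)
    t2 = extract_static_features(tiny_cohort[::-1])
    np.testing.assert_allclose(t1.values, t2.values[::-1], rtol=1e-12)
    assert t2.subject_ids == t1.subject_ids[::-1]
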