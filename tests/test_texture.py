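"""GLCM and Haralick statistics against exhaustive brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cellcycle3d.features.texture import (
    OFFSETS,
    STAT_NAMES,
    glcm_13,
    haralick_from_matrix,
    haralick_stats,
    quantize,
    texture_features,
)
from conftest import make_object, random_small_object


# ------------------------------------------------------------------ oracles

def naive_glcm(q, mask, levels, displacement=1):
    """Exhaustive O(n·26) pair enumeration, independent of the implementation."""
    mats = np.zeros((13, levels, levels))
    nz, ny, nx = mask.shape
    for k, (dz, dy, dx) in enumerate(OFFSETS):
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    if not mask[z, y, x]:
                        continue
                    z2, y2, x2 = z + dz * displacement, y + dy * displacement, x + dx * displacement
                    if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                        mats[k, q[z, y, x], q[z2, y2, x2]] += 1
                        mats[k, q[z2, y2, x2], q[z, y, x]] += 1
        total = mats[k].sum()
        if total:
            mats[k] /= total
    return mats


def naive_haralick(P):
    """Plain double-sum evaluation of the 16 statistics."""
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(L))
    sx, sy = var_x**0.5, var_y**0.5
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def xlogx(v):
        return v * np.log(v) if v > 0 else 0.0

    out = {}
    out["energy"] = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    out["entropy"] = -sum(xlogx(P[i, j]) for i in range(L) for j in range(L))
    if sx > 0 and sy > 0:
        out["correlation"] = sum(
            (i - mu_x) * (j - mu_y) * P[i, j] for i in range(L) for j in range(L)
        ) / (sx * sy)
    else:
        out["correlation"] = 0.0
    out["contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    out["homogeneity"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    out["variance"] = var_x
    sum_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    out["sum_average"] = sum_avg
    out["sum_variance"] = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    out["sum_entropy"] = -sum(xlogx(p_sum[k]) for k in range(2 * L - 1))
    out["difference_entropy"] = -sum(xlogx(p_diff[k]) for k in range(L))
    mu_d = sum(k * p_diff[k] for k in range(L))
    out["difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(L))
    out["cluster_shade"] = sum(
        (i + j - mu_x - mu_y) ** 3 * P[i, j] for i in range(L) for j in range(L))
    out["cluster_prominence"] = sum(
        (i + j - mu_x - mu_y) ** 4 * P[i, j] for i in range(L) for j in range(L))
    out["max_probability"] = max(P[i, j] for i in range(L) for j in range(L))
    HX = -sum(xlogx(v) for v in px)
    HY = -sum(xlogx(v) for v in py)
    HXY = out["entropy"]
    HXY1 = -sum(P[i, j] * np.log(px[i] * py[j])
                for i in range(L) for j in range(L) if P[i, j] > 0)
    HXY2 = -sum(xlogx(px[i] * py[j]) for i in range(L) for j in range(L))
    denom = max(HX, HY)
    out["imc1"] = (HXY - HXY1) / denom if denom > 0 else 0.0
    out["imc2"] = max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY))) ** 0.5
    return out


# ----------------------------------------------------------------- quantize

def test_quantize_identity_for_full_range_8bit():
    inten = np.arange(256, dtype=float).reshape(1, 16, 16)
    obj = make_object(np.ones_like(inten, bool), inten, voxel_size=(1, 1, 1))
    q = quantize(obj, 256)
    np.testing.assert_array_equal(q.ravel(), np.arange(256))


def test_quantize_constant_maps_to_zero():
    obj = make_object(np.ones((2, 2, 2), bool), np.full((2, 2, 2), 55.0),
                      voxel_size=(1, 1, 1))
    assert quantize(obj, 256).max() == 0


def test_quantize_half_open_binning():
    inten = np.array([10.0, 20.0, 30.0]).reshape(1, 1, 3)
    obj = make_object(np.ones((1, 1, 3), bool), inten, voxel_size=(1, 1, 1))
    np.testing.assert_array_equal(quantize(obj, 2).ravel(), [0, 1, 1])


def test_quantize_rejects_single_level():
    obj = make_object(np.ones((1, 1, 2), bool), voxel_size=(1, 1, 1))
    with pytest.raises(ValueError):
        quantize(obj, 1)


# ----------------------------------------------------------------- glcm_13

def test_two_voxel_object_single_direction():
    mask = np.ones((1, 1, 2), dtype=bool)
    q = np.array([[[3, 7]]])
    glcms = glcm_13(q, mask, levels=8)
    k = OFFSETS.index((0, 0, 1))
    expected = np.zeros((8, 8))
    expected[3, 7] = expected[7, 3] = 0.5
    np.testing.assert_allclose(glcms.matrices[k], expected)
    assert not glcms.empty[k]
    assert glcms.empty.sum() == 12


def test_constant_object_all_entries_at_origin():
    mask = np.ones((3, 3, 3), dtype=bool)
    glcms = glcm_13(np.zeros((3, 3, 3), int), mask, levels=4)
    for k in range(13):
        assert not glcms.empty[k]
        assert glcms.matrices[k][0, 0] == 1.0
        assert glcms.matrices[k].sum() == 1.0


def test_too_small_object_raises():
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    with pytest.raises(ValueError, match="no valid pairs"):
        glcm_13(np.zeros((3, 3, 3), int), mask, levels=4)


def test_glcm_matches_bruteforce_enumeration(rng):
    for _ in range(10):
        obj, levels = random_small_object(rng, max_side=4, levels=8)
        q = quantize(obj, levels)
        glcms = glcm_13(q, obj.mask, levels=levels)
        ref = naive_glcm(q, obj.mask, levels)
        np.testing.assert_allclose(glcms.matrices, ref, atol=1e-15)


def test_normalized_symmetric_and_marginals_equal(rng):
    obj, levels = random_small_object(rng, max_side=6, levels=8)
    glcms = glcm_13(quantize(obj, levels), obj.mask, levels=levels)
    for k in range(13):
        if glcms.empty[k]:
            continue
        P = glcms.matrices[k]
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T)
        np.testing.assert_allclose(P.sum(axis=0), P.sum(axis=1))


# ------------------------------------------------------------ haralick

def test_delta_matrix_identities():
    P = np.zeros((4, 4))
    P[0, 0] = 1.0
    s = haralick_from_matrix(P)
    assert s["energy"] == 1.0
    assert s["entropy"] == 0.0
    assert s["contrast"] == 0.0
    assert s["homogeneity"] == 1.0
    assert s["max_probability"] == 1.0
    assert s["correlation"] == 0.0


def test_checkerboard_matrix_hand_values():
    P = np.zeros((2, 2))
    P[0, 1] = P[1, 0] = 0.5
    s = haralick_from_matrix(P)
    assert s["contrast"] == pytest.approx(1.0)
    assert s["energy"] == pytest.approx(0.5)
    assert s["entropy"] == pytest.approx(np.log(2))


def test_haralick_matches_naive_formulas(rng):
    for _ in range(10):
        obj, levels = random_small_object(rng, max_side=5, levels=8)
        glcms = glcm_13(quantize(obj, levels), obj.mask, levels=levels)
        for k in range(13):
            if glcms.empty[k]:
                continue
            fast = haralick_from_matrix(glcms.matrices[k])
            slow = naive_haralick(glcms.matrices[k])
            for name in STAT_NAMES:
                assert fast[name] == pytest.approx(slow[name], rel=1e-10, abs=1e-12), name


def test_aggregation_excludes_empty_directions():
    mask = np.ones((1, 1, 5), dtype=bool)  # only the x direction has pairs
    obj = make_object(mask, np.arange(5, dtype=float).reshape(1, 1, 5),
                      voxel_size=(1, 1, 1))
    feats = texture_features(obj, levels=4)
    # one direction contributes: std over directions must be 0, not diluted
    for name in STAT_NAMES:
        assert feats[f"{name}_std"] == 0.0


@given(scale=st.floats(0.5, 20.0), offset=st.floats(-50.0, 50.0))
def test_affine_intensity_rescaling_invariance(scale, offset):
    # continuous intensities: generic values keep clear of the quantization
    # bin edges, where floor() is legitimately sensitive to float rounding
    rng = np.random.default_rng(99)
    inten = rng.uniform(0, 200, size=(4, 4, 4))
    mask = np.ones((4, 4, 4), dtype=bool)
    a = texture_features(make_object(mask, inten, voxel_size=(1, 1, 1)), levels=8)
    b = texture_features(make_object(mask, scale * inten + offset,
                                     voxel_size=(1, 1, 1)), levels=8)
    for name in STAT_NAMES:
        assert a[f"{name}_mean"] == pytest.approx(b[f"{name}_mean"], rel=1e-9)


def test_inplane_rotation_permutes_directions_but_keeps_means(rng):
    inten = rng.integers(0, 255, size=(6, 6, 6)).astype(float)
    mask = np.ones((6, 6, 6), dtype=bool)
    a = texture_features(make_object(mask, inten, voxel_size=(1, 1, 1)), levels=8)
    rot = np.rot90(inten, axes=(1, 2)).copy()
    b = texture_features(make_object(mask, rot, voxel_size=(1, 1, 1)), levels=8)
    for name in STAT_NAMES:
        assert a[f"{name}_mean"] == pytest.approx(b[f"{name}_mean"], rel=1e-9)


def test_energy_entropy_bounds(rng):
    obj, levels = random_small_object(rng, max_side=6, levels=8)
    glcms = glcm_13(quantize(obj, levels), obj.mask, levels=levels)
    for k in range(13):
        if glcms.empty[k]:
            continue
        s = haralick_from_matrix(glcms.matrices[k])
        assert 0 < s["energy"] <= s["max_probability"] <= 1
        assert 0 <= s["entropy"] <= 2 * np.log(levels)
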