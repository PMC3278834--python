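import numpy as np
import pytest

from cellcycle3d.features.geometry import (
    eccentricities,
    geometric_features,
    sphericity,
    surface_area,
    surface_distance_stats,
    surface_voxels,
    volume,
)
from cellcycle3d.resample import IsotropicMask
from conftest import digitized_ball, digitized_ellipsoid, make_object


def _iso(mask, s=1.0):
    return IsotropicMask(mask=np.asarray(mask, bool), voxel_size=s)


# ---------------------------------------------------------------- volume

@pytest.mark.parametrize("n_voxels,voxel_size,expected", [
    (10, (0.1, 0.1, 0.44), 0.044),
    (1, (1, 1, 1), 1.0),
    (60, (1, 1, 1), 60.0),
])
def test_volume_is_count_times_voxel_volume(n_voxels, voxel_size, expected):
    mask = np.zeros((3, 4, 5), dtype=bool)
    mask.flat[:n_voxels] = True
    obj = make_object(mask, voxel_size=voxel_size)
    assert volume(obj) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------- surface area

def test_sphere_surface_within_five_percent():
    r = 20
    A = surface_area(_iso(digitized_ball(r)))
    assert A == pytest.approx(4 * np.pi * r**2, rel=0.05)


def test_slab_surface_within_five_percent():
    slab = np.zeros((3, 22, 22), dtype=bool)
    slab[1, 1:21, 1:21] = True
    A = surface_area(_iso(slab))
    assert A == pytest.approx(2 * 20 * 20 + 4 * 20, rel=0.05)


def test_single_voxel_face_count_is_six():
    one = np.zeros((3, 3, 3), dtype=bool)
    one[1, 1, 1] = True
    assert surface_area(_iso(one), estimator="face_count") == 6.0
    assert surface_area(_iso(one)) == 6.0  # weighted estimator falls back


def test_face_count_exact_for_box():
    box = np.ones((3, 4, 5), dtype=bool)
    assert surface_area(_iso(box), estimator="face_count") == pytest.approx(
        2 * (3 * 4 + 4 * 5 + 3 * 5))


def test_unknown_estimator_and_empty_mask():
    with pytest.raises(ValueError):
        surface_area(_iso(np.ones((2, 2, 2), bool)), estimator="mesh")
    with pytest.raises(ValueError):
        surface_area(_iso(np.zeros((2, 2, 2), bool)))


# ------------------------------------------------------------ sphericity

def test_sphericity_closed_forms():
    # continuous sphere
    r = 3.0
    assert sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2) == pytest.approx(1.0)
    # cube
    a = 2.0
    assert sphericity(a**3, 6 * a**2) == pytest.approx(np.pi ** (1 / 3) * 6 ** (2 / 3) / 6)
    # slab with analytic box area
    assert sphericity(400.0, 880.0) == pytest.approx(
        np.pi ** (1 / 3) * 2400.0 ** (2 / 3) / 880.0)
    with pytest.raises(ValueError):
        sphericity(0.0, 1.0)


# --------------------------------------------------------- eccentricity

def test_ball_eccentricities_near_one():
    obj = make_object(digitized_ball(15), voxel_size=(1, 1, 1))
    e1, e2 = eccentricities(obj)
    assert e1 == pytest.approx(1.0, abs=0.05)
    assert e2 == pytest.approx(1.0, abs=0.05)
    assert e1 <= e2 <= 1.0


def test_ellipsoid_eccentricities_match_axis_ratios():
    # semi-axes (8, 4, 4): eigenvalues scale as squared semi-axes
    obj = make_object(digitized_ellipsoid((8, 4, 4)), voxel_size=(1, 1, 1))
    e1, e2 = eccentricities(obj)
    assert e1 == pytest.approx(0.5, abs=0.05)
    assert e2 == pytest.approx(0.5, abs=0.05)


def test_flat_disc_is_rank_deficient():
    disc = np.zeros((3, 31, 31), dtype=bool)
    ax = np.arange(31) - 15
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    disc[1] = yy**2 + xx**2 <= 14**2
    e1, e2 = eccentricities(make_object(disc, voxel_size=(1, 1, 1)))
    assert e1 < 0.1
    assert e2 > 0.9


def test_eccentricity_needs_two_voxels():
    one = np.zeros((3, 3, 3), dtype=bool)
    one[1, 1, 1] = True
    with pytest.raises(ValueError):
        eccentricities(make_object(one, voxel_size=(1, 1, 1)))


def test_anisotropic_voxels_enter_in_physical_units():
    # a 4x4x1-voxel plate at (1, 1, 4) µm voxels is physically a 4x4x4 slab
    mask = np.ones((1, 4, 4), dtype=bool)
    e1, e2 = eccentricities(make_object(mask, voxel_size=(1, 1, 4)))
    # z variance is 0 (single layer): flat in z regardless of spacing
    assert e1 == pytest.approx(0.0, abs=1e-9)
    assert e2 == pytest.approx(1.0, abs=1e-9)


# --------------------------------------------- surface-to-centroid stats

def test_sphere_surface_distances():
    r = 15
    obj = make_object(digitized_ball(r), voxel_size=(1, 1, 1))
    mu, sd = surface_distance_stats(obj)
    assert mu == pytest.approx(r, abs=0.5)
    assert sd <= 0.5


def test_single_voxel_distances_are_zero():
    one = np.zeros((3, 3, 3), dtype=bool)
    one[1, 1, 1] = True
    mu, sd = surface_distance_stats(make_object(one, voxel_size=(1, 1, 1)))
    assert mu == 0.0 and sd == 0.0


def test_rod_distances_by_enumeration():
    rod = np.ones((1, 1, 11), dtype=bool)
    mu, sd = surface_distance_stats(make_object(rod, voxel_size=(1, 1, 1)))
    d = np.abs(np.arange(11) - 5.0)
    assert mu == pytest.approx(d.mean(), rel=1e-12)  # 30/11
    assert sd == pytest.approx(d.std(), rel=1e-12)


def test_surface_voxels_border_counts_as_outside():
    box = np.ones((3, 3, 3), dtype=bool)
    surf = surface_voxels(box)
    assert surf.sum() == 26  # all but the centre voxel


# ------------------------------------------------- invariance properties

def test_features_invariant_to_translation_and_z_rotation():
    mask = np.zeros((24, 24, 24), dtype=bool)
    mask[4:12, 5:15, 6:13] = True
    mask[8:10, 10:20, 6:10] = True
    obj = make_object(mask, voxel_size=(1, 1, 1))
    ref = geometric_features(obj)
    shifted = geometric_features(make_object(
        np.roll(mask, (3, 2, 1), axis=(0, 1, 2)), voxel_size=(1, 1, 1)))
    rotated = geometric_features(make_object(
        np.rot90(mask, axes=(1, 2)), voxel_size=(1, 1, 1)))
    for other in (shifted, rotated):
        for attr in ("volume", "surface_area", "sphericity", "eccentricity_e1",
                     "eccentricity_e2", "dist_mean", "dist_std"):
            assert getattr(other, attr) == pytest.approx(getattr(ref, attr), rel=1e-9)


def test_big_sphere_invariant_suite():
    obj = make_object(digitized_ball(20), voxel_size=(1, 1, 1))
    f = geometric_features(obj)
    assert 0.95 <= f.sphericity <= 1.05
    assert 0.95 <= f.eccentricity_e1 <= 1.0
    assert 0.95 <= f.eccentricity_e2 <= 1.0
    assert f.dist_std / f.dist_mean <= 0.05


def test_ball_maximizes_sphericity_at_fixed_volume():
    shapes = {
        "ball": digitized_ball(10),
        "prolate": digitized_ellipsoid((17, 8, 8)),
        "oblate": digitized_ellipsoid((5, 15, 15)),
        "plate": digitized_ellipsoid((3, 18, 18)),
    }
    psi = {}
    for name, mask in shapes.items():
        obj = make_object(mask, voxel_size=(1, 1, 1))
        f = geometric_features(obj)
        psi[name] = f.sphericity
    assert all(psi["ball"] > v for k, v in psi.items() if k != "ball")
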