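"""Per-object 3D feature extraction: geometry, intensity and texture.

The canonical registry orders the features as 7 geometric, 5 intensity
(mean, std and the three signed centroid-deviation components) and 32
texture columns.  The full table carries 44 columns; the canonical
42-feature subset counts the centroid deviation once (z only, the
biologically informative apical–basal component), dropping ``cdev_x`` and
``cdev_y``.
"""

from __future__ import annotations

from .geometry import (
    GeometricFeatures,
    calibrate_surface_weights,
    count_configurations,
    eccentricities,
    geometric_features,
    sphericity,
    surface_area,
    surface_distance_stats,
    surface_voxels,
    volume,
)
from .intensity import IntensityFeatures, centroid_deviation, intensity_features, intensity_stats
from .texture import (
    GLCMSet,
    OFFSETS,
    STAT_NAMES,
    TextureFeatures,
    glcm_13,
    haralick_from_matrix,
    haralick_stats,
    quantize,
    texture_features,
)

GEOMETRIC_FEATURES: tuple[str, ...] = (
    "volume", "surface_area", "sphericity",
    "eccentricity_e1", "eccentricity_e2", "dist_mean", "dist_std",
)

INTENSITY_FEATURES: tuple[str, ...] = ("int_mean", "int_std", "cdev_x", "cdev_y", "cdev_z")

TEXTURE_FEATURES: tuple[str, ...] = tuple(
    f"{name}_{agg}" for name in STAT_NAMES for agg in ("mean", "std")
)

#: All 44 extracted columns in canonical order.
ALL_FEATURES: tuple[str, ...] = GEOMETRIC_FEATURES + INTENSITY_FEATURES + TEXTURE_FEATURES

#: The canonical 42-feature set (centroid deviation counted once, z only).
FEATURES_42: tuple[str, ...] = tuple(f for f in ALL_FEATURES if f not in ("cdev_x", "cdev_y"))

#: Reduced feature preset for final classifier training: sphericity, surface
#: area, five dominant texture statistics, intensity std and the z centroid
#: deviation (eight names; the source list for the nine-feature set
#: enumerates only these eight).
PAPER9_FEATURES: tuple[str, ...] = (
    "sphericity", "surface_area", "homogeneity_mean", "imc1_mean",
    "difference_variance_mean", "entropy_mean", "int_std", "cdev_z",
)


def extract_features(obj, levels: int = 256, displacement: int = 1,
                     surface_estimator: str = "weighted") -> dict[str, float]:
    """All 44 features of one labelled object as a name → value mapping."""
    geo = geometric_features(obj, estimator=surface_estimator)
    inten = intensity_features(obj)
    tex = texture_features(obj, levels=levels, displacement=displacement)
    out = {
        "volume": geo.volume,
        "surface_area": geo.surface_area,
        "sphericity": geo.sphericity,
        "eccentricity_e1": geo.eccentricity_e1,
        "eccentricity_e2": geo.eccentricity_e2,
        "dist_mean": geo.dist_mean,
        "dist_std": geo.dist_std,
        "int_mean": inten.mean,
        "int_std": inten.std,
        "cdev_x": inten.centroid_dev[0],
        "cdev_y": inten.centroid_dev[1],
        "cdev_z": inten.centroid_dev[2],
    }
    out.update(tex.values)
    return out
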