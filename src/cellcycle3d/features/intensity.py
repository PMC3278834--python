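"""Intensity features: mean/std and the intensity-centroid deviation.

The centroid deviation — the vector from the geometric centroid of the
object's voxels to its intensity-weighted centroid — captures asymmetric
intensity distributions such as the condensed heterochromatin found at one
end of an interphase nucleus.  Signed components are stored (the sign
carries orientation); deviations are in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IntensityFeatures:
    mean: float
    std: float
    centroid_dev: tuple[float, float, float]  # (dx, dy, dz) in µm


def intensity_stats(obj) -> tuple[float, float]:
    """Mean and population standard deviation of intensities over mask voxels."""
    vals = obj.intensity[obj.mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    vals = vals.astype(float)
    return float(vals.mean()), float(vals.std())


def centroid_deviation(obj) -> tuple[float, float, float]:
    """Intensity-weighted minus geometric centroid, as (dx, dy, dz) in µm.

    The geometric centroid is the unweighted mean of the physical voxel
    centres; the weighted centroid uses voxel intensities as weights.
    """
    mask = obj.mask
    weights = obj.intensity[mask].astype(float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero intensity inside mask: weighted centroid undefined")
    coords = obj.physical_coords()  # (n, 3) in (z, y, x) µm
    geometric = coords.mean(axis=0)
    weighted = (coords * weights[:, None]).sum(axis=0) / total
    dz, dy, dx = weighted - geometric
    return (float(dx), float(dy), float(dz))


def intensity_features(obj) -> IntensityFeatures:
    mu, sd = intensity_stats(obj)
    return IntensityFeatures(mean=mu, std=sd, centroid_dev=centroid_deviation(obj))
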