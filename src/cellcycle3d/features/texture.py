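"""3D Haralick texture features from 13-direction co-occurrence matrices.

The classic grey-level co-occurrence matrix (GLCM) is extended to 3D by
counting co-occurrences along the 13 unique directions of the
26-neighbourhood at displacement 1.  Only voxel pairs that both lie inside
the object mask are counted, so the texture describes the object and not
its background.  Sixteen scalar statistics are computed per direction and
summarised as their mean and population standard deviation over the
non-empty directions, giving 32 texture features per object.

Intensities are quantized per object by min–max rescaling to ``levels``
grey levels (default 256), which makes every statistic invariant to affine
rescaling of the raw intensities.  Offsets are in voxel units; the physical
anisotropy of the z step is a documented, deliberate bias (the native
acquisition convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 13 unique displacement directions of the 3D 26-neighbourhood,
#: as (dz, dy, dx) voxel offsets.
OFFSETS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1),
)

#: Canonical order of the 16 Haralick statistics.
STAT_NAMES: tuple[str, ...] = (
    "energy", "entropy", "correlation", "contrast", "homogeneity",
    "variance", "sum_entropy", "sum_average", "sum_variance",
    "difference_entropy", "cluster_shade", "cluster_prominence",
    "difference_variance", "max_probability", "imc1", "imc2",
)


@dataclass(frozen=True)
class GLCMSet:
    """13 direction-wise, symmetrized, sum-1-normalized co-occurrence matrices."""

    matrices: np.ndarray          # (13, levels, levels)
    empty: np.ndarray             # (13,) bool; True where no valid pair exists
    levels: int
    displacement: int

    def __post_init__(self) -> None:
        if self.matrices.shape != (len(OFFSETS), self.levels, self.levels):
            raise ValueError("matrices must be (13, levels, levels)")


@dataclass(frozen=True)
class TextureFeatures:
    """Mean and population std over directions for each of the 16 statistics."""

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def quantize(obj, levels: int = 256) -> np.ndarray:
    """Quantize mask-voxel intensities to integer bins 0..levels−1.

    Linear min–max binning over the mask, ``floor((I − min)/(max − min) ·
    levels)`` clipped to ``levels − 1``; a constant-intensity object maps
    to bin 0 everywhere.  Returns an int array of the crop shape (values
    outside the mask are 0 and never used).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    vals = obj.intensity[obj.mask].astype(float)
    lo, hi = vals.min(), vals.max()
    q = np.zeros(obj.mask.shape, dtype=np.int32)
    if hi > lo:
        binned = np.floor((obj.intensity.astype(float) - lo) / (hi - lo) * levels)
        q[obj.mask] = np.clip(binned[obj.mask], 0, levels - 1).astype(np.int32)
    return q


def glcm_13(quantized: np.ndarray, mask: np.ndarray, levels: int = 256,
            displacement: int = 1) -> GLCMSet:
    """Co-occurrence matrices along the 13 directions at the given displacement.

    For each offset, ordered pairs (v, v+offset) with both voxels inside
    the mask are counted; the transpose is added (symmetrization) and the
    matrix normalized to sum 1.  Directions without a single valid pair
    yield an all-zero matrix flagged empty; if *every* direction is empty
    the object is too small and an error lists them.
    """
    if displacement < 1:
        raise ValueError("displacement must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    q = np.asarray(quantized)
    mats = np.zeros((len(OFFSETS), levels, levels))
    empty = np.zeros(len(OFFSETS), dtype=bool)
    for k, (dz, dy, dx) in enumerate(OFFSETS):
        off = (dz * displacement, dy * displacement, dx * displacement)
        sl_a, sl_b = _offset_slices(mask.shape, off)
        valid = mask[sl_a] & mask[sl_b]
        if not valid.any():
            empty[k] = True
            continue
        a = q[sl_a][valid].ravel()
        b = q[sl_b][valid].ravel()
        counts = np.bincount(a * levels + b, minlength=levels * levels)
        P = counts.reshape(levels, levels).astype(float)
        P = P + P.T
        mats[k] = P / P.sum()
    if empty.all():
        names = [OFFSETS[k] for k in range(len(OFFSETS))]
        raise ValueError(f"object too small: no valid pairs in any direction {names}")
    return GLCMSet(matrices=mats, empty=empty, levels=levels, displacement=displacement)


def _offset_slices(shape, offset):
    sl_a, sl_b = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def haralick_from_matrix(P: np.ndarray) -> dict[str, float]:
    """The 16 Haralick statistics of one normalized, symmetric GLCM.

    Conventions: 0·log 0 = 0 (natural logarithm throughout); correlation
    and information measure 1 return 0 in their degenerate cases
    (σx·σy = 0, HX = HY = 0).  HXY2 is computed through the product-marginal
    identity HXY2 = HX + HY, exact for normalized marginals.
    """
    L = P.shape[0]
    flat = P.ravel()
    nz = np.nonzero(flat)[0]
    p = flat[nz]
    i = nz // L
    j = nz % L

    px = np.bincount(i, weights=p, minlength=L)
    px = px  # symmetric matrix: py == px
    idx = np.arange(L, dtype=float)
    mu_x = float(idx @ px)
    var_x = float(((idx - mu_x) ** 2) @ px)
    sigma_x = np.sqrt(var_x)

    p_sum = np.bincount(i + j, weights=p, minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(i - j), weights=p, minlength=L)
    ks = np.arange(p_sum.size, dtype=float)
    kd = np.arange(p_diff.size, dtype=float)

    energy = float(p @ p)
    entropy = float(-(p @ np.log(p)))
    contrast = float((kd**2) @ p_diff)
    homogeneity = float((p_diff / (1.0 + kd**2)).sum())
    if sigma_x > 0:
        correlation = float((((i - mu_x) * (j - mu_x) * p).sum()) / (sigma_x * sigma_x))
    else:
        correlation = 0.0
    variance = var_x
    sum_average = float(ks @ p_sum)
    sum_variance = float(((ks - sum_average) ** 2) @ p_sum)
    nz_s = p_sum > 0
    sum_entropy = float(-(p_sum[nz_s] @ np.log(p_sum[nz_s])))
    nz_d = p_diff > 0
    difference_entropy = float(-(p_diff[nz_d] @ np.log(p_diff[nz_d])))
    mu_diff = float(kd @ p_diff)
    difference_variance = float(((kd - mu_diff) ** 2) @ p_diff)
    cluster_shade = float(((ks - 2 * mu_x) ** 3) @ p_sum)
    cluster_prominence = float(((ks - 2 * mu_x) ** 4) @ p_sum)
    max_probability = float(p.max())

    nz_x = px > 0
    HX = float(-(px[nz_x] @ np.log(px[nz_x])))
    HXY = entropy
    HXY1 = float(-(p @ (np.log(px[i]) + np.log(px[j]))))
    HXY2 = 2.0 * HX  # HX + HY with identical marginals
    imc1 = (HXY - HXY1) / HX if HX > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))

    return {
        "energy": energy, "entropy": entropy, "correlation": correlation,
        "contrast": contrast, "homogeneity": homogeneity, "variance": variance,
        "sum_entropy": sum_entropy, "sum_average": sum_average,
        "sum_variance": sum_variance, "difference_entropy": difference_entropy,
        "cluster_shade": cluster_shade, "cluster_prominence": cluster_prominence,
        "difference_variance": difference_variance,
        "max_probability": max_probability, "imc1": imc1, "imc2": float(imc2),
    }


def haralick_stats(glcms: GLCMSet) -> TextureFeatures:
    """Aggregate the 16 statistics as mean and population std over the
    non-empty directions (empty directions are excluded, not zero-imputed,
    so thin objects do not inherit orientation artefacts)."""
    keep = ~glcms.empty
    if not keep.any():
        raise ValueError("all GLCM directions are empty")
    per_dir = [haralick_from_matrix(glcms.matrices[k]) for k in np.nonzero(keep)[0]]
    out: dict[str, float] = {}
    for name in STAT_NAMES:
        vals = np.array([d[name] for d in per_dir])
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_std"] = float(vals.std())
    return TextureFeatures(values=out)


def texture_features(obj, levels: int = 256, displacement: int = 1) -> TextureFeatures:
    """Quantize, build the 13 GLCMs and aggregate the Haralick statistics."""
    q = quantize(obj, levels=levels)
    glcms = glcm_13(q, obj.mask, levels=levels, displacement=displacement)
    return haralick_stats(glcms)
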