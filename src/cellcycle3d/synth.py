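"""Synthetic 3D nucleus phantoms in five cell-cycle morphologies.

Every pipeline stage is testable without microscopy data: the generator
renders histone-GFP-like nuclei as parametric solids on an anisotropic
voxel grid (default 0.1 × 0.1 × 0.44 µm), with Poisson shot noise plus
Gaussian read noise, and returns the intensity stack, the ground-truth
label mask (segmentation is an upstream input, so the analytic mask plays
that role) and a phase table.

Morphologies mirror chromatin appearance through the division cycle:

* **interphase** — near-spherical envelope (~4 µm diameter), smooth
  low-contrast interior, usually with an off-centre bright subregion along
  z (condensed heterochromatin at one end of the nucleus);
* **prophase** — similar envelope, slightly condensed, high-contrast
  internal speckle (condensing chromosomes);
* **metaphase** — bright oblate plate (one short axis);
* **anaphase** — two partially separated bright lobes along a random axis;
* **telophase** — two compact, well-separated decondensing blobs kept as a
  single object.

Class frequencies default to the interphase-dominant mix observed in live
embryos (58% interphase; prophase and anaphase are ~4–5% minorities), and
parameter ranges of adjacent phases overlap deliberately — phase
transitions are gradual and there are no sharp morphological boundaries —
so minority phases are genuinely confusable, which is exactly the regime
the class-weighting rule addresses.

A :class:`StageShift` emulates a developmental covariate shift: upon
cellularization epithelial nuclei elongate along the apical–basal (z) axis
and acquisition gain may differ between recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dataset import PHASES, PhaseDataset, assemble
from .stack_io import LabelMask, VoxelGrid, extract_objects

#: Interphase-dominant default class mix (interphase, prophase, metaphase,
#: anaphase, telophase).
DEFAULT_MIX: dict[str, float] = {
    "interphase": 0.58, "prophase": 0.04, "metaphase": 0.13,
    "anaphase": 0.05, "telophase": 0.20,
}

DEFAULT_VOXEL_SIZE = (0.1, 0.1, 0.44)  # (sx, sy, sz) µm

#: Side of the per-nucleus rendering box in µm (fits the largest telophase
#: phantom at any orientation, with margin).
BOX_UM = 10.8


@dataclass(frozen=True)
class PhasePhantomSpec:
    """Sampling ranges for one phase's phantom family.

    ``radius`` is the base envelope radius in µm (Gaussian with the given
    sd, truncated to ±2 sd); ``contrast`` the internal speckle amplitude
    relative to the mean; ``brightness`` the intensity scale relative to the
    interphase base level.  Two-lobe phases use ``lobe_frac`` (lobe radius
    as a fraction of the base radius) and ``separation`` (centre distance
    in units of the base radius).
    """

    phase: str
    radius: tuple[float, float] = (2.0, 0.15)
    contrast: tuple[float, float] = (0.18, 0.10)
    brightness: float = 1.0
    flattening: tuple[float, float] | None = None      # short-axis fraction (metaphase)
    lobe_frac: float | None = None
    separation: tuple[float, float] | None = None
    blob_prob: float = 0.0                              # heterochromatin subregion
    random_orientation: bool = True


#: Default phantom families.  Adjacent phases share boundary morphologies on
#: purpose: prophase speckle contrast overlaps the upper interphase range
#: (gradual chromosome condensation) and the anaphase lobe-separation range
#: overlaps the lower telophase range (progressive sister-chromatid
#: separation), so the minority phases are confusable with their dominant
#: neighbours to a degree comparable with live-embryo data.
DEFAULT_PHANTOMS: dict[str, PhasePhantomSpec] = {
    "interphase": PhasePhantomSpec(
        phase="interphase", radius=(2.0, 0.15), contrast=(0.20, 0.10),
        brightness=1.0, blob_prob=0.70, random_orientation=False),
    "prophase": PhasePhantomSpec(
        phase="prophase", radius=(2.0, 0.15), contrast=(0.42, 0.16),
        brightness=1.10),
    "metaphase": PhasePhantomSpec(
        phase="metaphase", radius=(1.9, 0.15), contrast=(0.30, 0.10),
        brightness=1.30, flattening=(0.33, 0.07)),
    "anaphase": PhasePhantomSpec(
        phase="anaphase", radius=(1.9, 0.15), contrast=(0.38, 0.12),
        brightness=1.25, lobe_frac=0.65, separation=(1.65, 0.40)),
    "telophase": PhasePhantomSpec(
        phase="telophase", radius=(2.0, 0.15), contrast=(0.30, 0.10),
        brightness=1.00, lobe_frac=0.64, separation=(2.00, 0.35)),
}

BASE_INTENSITY = 400.0
BACKGROUND = 40.0
BLOB_BOOST = 1.8
READ_NOISE = 8.0


@dataclass(frozen=True)
class StageShift:
    """Bounded, seed-reproducible developmental-stage covariate shift.

    ``elongation_z`` stretches interphase envelopes along z (apical–basal
    elongation after cellularization, round → oval); ``size_scale`` scales
    all envelopes; ``gain`` scales the fluorescence signal (laser power /
    detector gain differences between recordings); ``texture_shift`` adds
    to every phase's speckle contrast.
    """

    elongation_z: float = 1.0
    size_scale: float = 1.0
    gain: float = 1.0
    texture_shift: float = 0.0


STAGE_PRESETS: dict[str, StageShift] = {
    "none": StageShift(),
    "A": StageShift(),                       # syncytium-like reference stage
    "B": StageShift(elongation_z=1.6, size_scale=1.10, gain=1.5, texture_shift=0.10),
}


def _trunc_normal(rng, mean, sd, lo=None, hi=None) -> float:
    lo = mean - 2 * sd if lo is None else lo
    hi = mean + 2 * sd if hi is None else hi
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _render_box(rng, phase: str | None, spec_map, stage: StageShift,
                box_shape, voxel_size) -> np.ndarray:
    """Render one box: intensity with noise; returns (intensity, mask)."""
    sx, sy, sz = voxel_size
    spacing = np.array([sz, sy, sx])
    nz, ny, nx = box_shape
    if phase is None:
        photons = rng.poisson(BACKGROUND, size=box_shape).astype(float)
        noisy = photons + rng.normal(0.0, READ_NOISE, size=box_shape)
        return np.clip(noisy, 0, 65535).astype(np.uint16), np.zeros(box_shape, bool)

    spec: PhasePhantomSpec = spec_map[phase]
    r = _trunc_normal(rng, *spec.radius) * stage.size_scale
    contrast = max(0.02, _trunc_normal(rng, *spec.contrast) + stage.texture_shift)
    gain_obj = stage.gain * rng.uniform(0.85, 1.15)

    # physical coordinates of voxel centres relative to the (jittered) centre
    centre = (np.array(box_shape) - 1) / 2.0 * spacing
    centre += rng.uniform([-0.3, -0.5, -0.5], [0.3, 0.5, 0.5])
    ax = [(np.arange(n) * s - c) for n, s, c in zip(box_shape, spacing, centre)]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij", sparse=False)
    P = np.stack([zz, yy, xx], axis=-1)  # (nz, ny, nx, 3) physical offsets

    blob_mask = None
    if spec.lobe_frac is not None:
        sep = _trunc_normal(rng, *spec.separation) * r
        lobe = spec.lobe_frac * r
        axis = _random_rotation(rng)[:, 0]
        jit = rng.uniform(0.9, 1.1, size=2)
        d1 = np.linalg.norm(P - (axis * sep / 2), axis=-1)
        d2 = np.linalg.norm(P + (axis * sep / 2), axis=-1)
        mask = (d1 <= lobe * jit[0]) | (d2 <= lobe * jit[1])
    elif spec.flattening is not None:
        c_frac = _trunc_normal(rng, *spec.flattening)
        axes = np.array([c_frac * r, r * rng.uniform(0.9, 1.1), r * rng.uniform(0.9, 1.1)])
        R = _random_rotation(rng) if spec.random_orientation else np.eye(3)
        Q = P @ R
        mask = ((Q / axes) ** 2).sum(axis=-1) <= 1.0
    else:
        jit = rng.uniform(0.92, 1.08, size=2)
        axes = np.array([r * stage.elongation_z if spec.phase == "interphase" else r,
                         r * jit[0], r * jit[1]])
        if spec.random_orientation:
            Q = P @ _random_rotation(rng)
        else:
            Q = P
        mask = ((Q / axes) ** 2).sum(axis=-1) <= 1.0
        if spec.blob_prob and rng.uniform() < spec.blob_prob:
            off = np.array([axes[0] * 0.55 * rng.choice([-1.0, 1.0]), 0.0, 0.0])
            blob_r = 0.35 * r
            blob_mask = np.linalg.norm(P - off, axis=-1) <= blob_r

    if not mask.any():  # pathological draw; fall back to a centred ball
        mask = np.linalg.norm(P, axis=-1) <= max(r, 2 * max(voxel_size))

    # speckle texture: smoothed white noise normalized to the drawn contrast
    sigma_vox = 0.25 / spacing  # ~0.25 µm correlation length
    field = gaussian_filter(rng.normal(size=box_shape), sigma=sigma_vox)
    sd = field.std()
    if sd > 0:
        field *= contrast / sd
    signal = BASE_INTENSITY * spec.brightness * gain_obj * np.clip(1.0 + field, 0.05, None)
    intensity = np.full(box_shape, BACKGROUND)
    intensity[mask] = BACKGROUND + signal[mask]
    if blob_mask is not None:
        boost = blob_mask & mask
        intensity[boost] *= BLOB_BOOST
    photons = rng.poisson(np.clip(intensity, 0, None)).astype(float)
    noisy = photons + rng.normal(0.0, READ_NOISE, size=box_shape)
    return np.clip(noisy, 0, 65535).astype(np.uint16), mask


def generate_dataset(n: int, mix: dict[str, float] | None = None,
                     stage: StageShift | str | None = None,
                     voxel_size=DEFAULT_VOXEL_SIZE, seed: int = 0,
                     phantom_specs: dict[str, PhasePhantomSpec] | None = None,
                     max_voxels: int = 2_200_000_000):
    """Generate a labelled synthetic stack.

    Phantoms are placed on a non-overlapping grid of rendering boxes
    (one z-layer of nuclei, like an embryo surface).  Returns
    ``(VoxelGrid, LabelMask, truth)`` where ``truth`` is a DataFrame with
    columns ``stack_id, object_id, phase``.

    ``mix`` maps phase → proportion (must sum to 1); ``stage`` is a
    :class:`StageShift`, a preset name ("none", "A", "B") or None.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(DEFAULT_MIX if mix is None else mix)
    if set(mix) != set(PHASES):
        raise ValueError(f"mix must cover exactly the phases {PHASES}")
    props = np.array([mix[p] for p in PHASES], dtype=float)
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("mix proportions must sum to 1")
    if stage is None:
        stage = StageShift()
    elif isinstance(stage, str):
        stage = STAGE_PRESETS[stage]
    specs = DEFAULT_PHANTOMS if phantom_specs is None else phantom_specs

    rng = np.random.default_rng(seed)
    sx, sy, sz = voxel_size
    box_shape = (int(np.ceil(BOX_UM / sz)), int(np.ceil(BOX_UM / sy)),
                 int(np.ceil(BOX_UM / sx)))
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    shape = (box_shape[0], rows * box_shape[1], cols * box_shape[2])
    if int(np.prod(shape)) > max_voxels:
        raise ValueError(
            f"n = {n} needs a {shape} stack ({np.prod(shape):.2e} voxels), "
            f"above the limit {max_voxels:.2e}")

    phases = rng.choice(len(PHASES), size=n, p=props)
    stack = np.zeros(shape, dtype=np.uint16)
    label_dtype = np.int16 if n < np.iinfo(np.int16).max else np.int32
    labels = np.zeros(shape, dtype=label_dtype)
    records = []
    for idx in range(rows * cols):
        rr, cc = divmod(idx, cols)
        sl = (slice(None),
              slice(rr * box_shape[1], (rr + 1) * box_shape[1]),
              slice(cc * box_shape[2], (cc + 1) * box_shape[2]))
        phase = PHASES[phases[idx]] if idx < n else None
        intensity, mask = _render_box(rng, phase, specs, stage, box_shape, voxel_size)
        stack[sl] = intensity
        if phase is not None:
            labels[sl][mask] = idx + 1
            records.append({"stack_id": "synthetic", "object_id": idx + 1, "phase": phase})
    grid = VoxelGrid(data=stack, voxel_size=tuple(voxel_size), bit_depth=16)
    truth = pd.DataFrame(records, columns=["stack_id", "object_id", "phase"])
    return grid, LabelMask(labels=labels), truth


def generate_phase_dataset(n: int, mix=None, stage=None,
                           voxel_size=DEFAULT_VOXEL_SIZE, seed: int = 0,
                           **assemble_kwargs) -> PhaseDataset:
    """Simulate, extract and assemble in one call: a labelled feature table."""
    grid, mask, truth = generate_dataset(n, mix=mix, stage=stage,
                                         voxel_size=voxel_size, seed=seed)
    objects = extract_objects(grid, mask)
    labels = {(row.stack_id, row.object_id): row.phase for row in truth.itertuples()}
    return assemble(objects, labels=labels, stack_id="synthetic", **assemble_kwargs)
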