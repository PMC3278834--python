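"""Reading, writing and decomposing 3D image stacks.

A stack is a multi-page TIFF in (z, y, x) axis order with physical voxel
sizes supplied by the caller (confocal TIFF tags are too dialect-dependent
to trust; conflicting tags only produce a warning).  A co-registered label
mask (integer labels, 0 = background) produced by any upstream segmenter is
decomposed into per-object records that carry the binary mask, the intensity
crop and the voxel geometry needed by every downstream feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D intensity stack with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities in (z, y, x) order.
    voxel_size : tuple of float
        Physical voxel extent ``(sx, sy, sz)`` in micrometres.  Note the
        (x, y, z) ordering of the sizes versus the (z, y, x) ordering of
        the array axes; :attr:`spacing_zyx` gives the array-aligned view.
    bit_depth : int
        8 or 16.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("stack must be a 3D array with non-empty axes")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be three strictly positive values")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}; expected 8 or 16")

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel spacing re-ordered to match the array axes (sz, sy, sx)."""
        sx, sy, sz = self.voxel_size
        return (sz, sy, sx)

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        sx, sy, sz = self.voxel_size
        return sx * sy * sz


@dataclass(frozen=True)
class LabelMask:
    """Integer label stack paired with a :class:`VoxelGrid`; 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("label mask must be 3D")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValueError("label mask must hold integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def object_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]


@dataclass(frozen=True)
class LabeledObject:
    """One segmented nucleus: tight binary crop + intensity crop + geometry.

    ``offset`` is the (z, y, x) origin of the crop in the full stack
    (0-based; bounding boxes are half-open).
    """

    object_id: int
    mask: np.ndarray
    intensity: np.ndarray
    offset: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.mask.shape != self.intensity.shape:
            raise ValueError("mask and intensity crops must share a shape")
        if not self.mask.any():
            raise ValueError(f"object {self.object_id} has an empty mask")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.voxel_size
        return (sz, sy, sx)

    def physical_coords(self) -> np.ndarray:
        """Physical (z, y, x) coordinates in µm of the mask voxel centres."""
        idx = np.argwhere(self.mask).astype(float)
        return idx * np.asarray(self.spacing_zyx)


def read_stack(path, voxel_size: tuple[float, float, float]) -> VoxelGrid:
    """Read a multi-page TIFF into a :class:`VoxelGrid`.

    TIFF pages map to z.  ``voxel_size`` is ``(sx, sy, sz)`` in µm and is
    always taken from the caller; resolution tags, if present and in
    conflict, trigger a warning only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise ValueError(f"mixed page shapes in {path}: {sorted(shapes)}")
        data = tif.asarray()
        _warn_on_conflicting_tags(tif, voxel_size, path)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.dtype == np.uint8:
        depth = 8
    elif data.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported bit depth (dtype {data.dtype}) in {path}; expected uint8 or uint16")
    return VoxelGrid(data=data, voxel_size=tuple(float(s) for s in voxel_size), bit_depth=depth)


def _warn_on_conflicting_tags(tif, voxel_size, path) -> None:
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is None:
            return
        num, den = xres.value
        if num == 0 or num == den:  # absent or placeholder 1:1 resolution
            return
        tag_sx = den / num  # µm/px if the writer used µm⁻¹ resolution units
        if abs(tag_sx - voxel_size[0]) > 1e-6 * max(tag_sx, voxel_size[0]):
            warnings.warn(
                f"{path}: TIFF resolution tag ({tag_sx:g}) disagrees with the "
                f"supplied x voxel size ({voxel_size[0]:g}); using the supplied value",
                stacklevel=3,
            )
    except Exception:  # tag dialects are unreliable; never fail on them
        pass


def write_stack(path, grid: VoxelGrid) -> None:
    """Write a :class:`VoxelGrid` as a multi-page TIFF (z as pages)."""
    tifffile.imwrite(Path(path), grid.data, photometric='minisblack')


def read_labels(path) -> LabelMask:
    """Read an integer label stack (multi-page TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[np.newaxis]
    return LabelMask(labels=labels.astype(np.int32, copy=False))


def write_labels(path, mask: LabelMask) -> None:
    tifffile.imwrite(Path(path), mask.labels.astype(np.int32, copy=False), photometric='minisblack')


def extract_objects(grid: VoxelGrid, mask: LabelMask) -> list[LabeledObject]:
    """Decompose a labelled stack into per-object crops.

    One :class:`LabeledObject` per nonzero label, cropped to the tight
    bounding box.  Labels are taken as the upstream segmenter left them:
    touching objects stay distinct and single-label connectivity is not
    enforced.  An all-zero mask yields an empty list.
    """
    if grid.data.shape != mask.labels.shape:
        raise ValueError(
            f"stack shape {grid.data.shape} does not match label shape {mask.labels.shape}"
        )
    labels = mask.labels
    slices = ndimage.find_objects(labels)
    out: list[LabeledObject] = []
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        crop = labels[sl] == lab
        out.append(
            LabeledObject(
                object_id=lab,
                mask=crop,
                intensity=np.ascontiguousarray(grid.data[sl]),
                offset=tuple(int(s.start) for s in sl),
                voxel_size=grid.voxel_size,
            )
        )
    return out
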