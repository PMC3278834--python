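"""Maximum-intensity-projection overlays for validating classifications.

The classification result is superimposed on the MIP of the stack: each
object's projected silhouette contour is drawn (red by default) with its
class code 1–5 at the projected centroid.  When ground truth is available,
correct predictions are printed in white and errors as "(predicted,
actual)" in black, so segmentation quality and classification performance
can be judged together.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage
from skimage import measure

from .dataset import PHASE_CODES
from .stack_io import LabelMask, VoxelGrid


@dataclass(frozen=True)
class OverlayStyle:
    contour_color: str = "red"
    correct_color: str = "white"
    error_color: str = "black"
    fontsize: int = 8
    dpi: int = 150


def render_overlay(grid: VoxelGrid, mask: LabelMask, predictions: dict,
                   truth: dict | None = None,
                   style: OverlayStyle = OverlayStyle(),
                   out_path=None) -> np.ndarray:
    """Render the MIP overlay; returns the RGB image array.

    ``predictions`` (and optional ``truth``) map object id → phase name.
    The MIP is contrast-stretched to its 1st–99th percentile for display
    only.  Writes a PNG when ``out_path`` is given.
    """
    ids = set(mask.object_ids)
    unknown = set(predictions) - ids
    if unknown:
        raise ValueError(f"predictions for unknown object ids: {sorted(unknown)}")

    mip = grid.data.max(axis=0).astype(float)
    lo, hi = np.percentile(mip, [1, 99])
    disp = np.clip((mip - lo) / max(hi - lo, 1e-9), 0, 1)

    h, w = disp.shape
    fig = plt.figure(figsize=(w / style.dpi, h / style.dpi), dpi=style.dpi)
    axp = fig.add_axes([0, 0, 1, 1])
    axp.imshow(disp, cmap="gray", vmin=0, vmax=1, interpolation="nearest")
    axp.set_axis_off()

    for oid in mask.object_ids:
        proj = (mask.labels == oid).any(axis=0)
        for contour in measure.find_contours(proj.astype(float), 0.5):
            axp.plot(contour[:, 1], contour[:, 0], color=style.contour_color, linewidth=0.8)
        if oid not in predictions:
            continue
        cy, cx = ndimage.center_of_mass(proj)
        pred_code = PHASE_CODES[predictions[oid]]
        if truth is None or oid not in truth:
            text, color = str(pred_code), style.correct_color
        else:
            true_code = PHASE_CODES[truth[oid]]
            if true_code == pred_code:
                text, color = str(pred_code), style.correct_color
            else:
                text, color = f"({pred_code},{true_code})", style.error_color
        axp.text(cx, cy, text, color=color, fontsize=style.fontsize,
                 ha="center", va="center")

    fig.canvas.draw()
    rgba = np.asarray(fig.canvas.buffer_rgba())
    if out_path is not None:
        fig.savefig(out_path, dpi=style.dpi)
    plt.close(fig)
    return rgba[..., :3].copy()
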