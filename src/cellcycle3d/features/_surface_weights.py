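"""Frozen 2x2x2 configuration weights for voxel-based surface-area estimation.

Produced by :func:`cellcycle3d.features.geometry.calibrate_surface_weights`
(seed 0, defaults) and frozen here.  Weights are per equivalence class of
the 48 orthogonal cube symmetries, keyed by the smallest configuration
index in each orbit, in units of the squared isotropic voxel spacing;
classes absent from the table (never observed on digitized half-spaces,
spheres or boxes) contribute zero area.
"""

from itertools import permutations, product

import numpy as np

_CLASS_WEIGHTS = {
    0b00000011: 1.0309248502228479,  # two voxels sharing a cell edge (step / thin-wall)
    0b00000111: 1.1630607377005808,  # three voxels, L on one face
    0b00001111: 1.0,  # four voxels filling one face (flat axis-aligned surface)
    0b00010111: 0.5719976229312812,  # four voxels, face corner plus opposite vertex
    0b00111111: 0.28644768199452686,  # six voxels (concave edge)
    0b01111111: 1.1511038213447218,  # seven voxels (concave corner)
}


def _orbit_labels() -> np.ndarray:
    corners = np.array(
        [(dz, dy, dx) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)], dtype=float
    )
    perms = []
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            mapped = (corners[:, perm] - 0.5) * np.array(signs) + 0.5
            perms.append((mapped @ np.array([4.0, 2.0, 1.0])).round().astype(int))
    labels = -np.ones(256, dtype=int)
    for cfg in range(256):
        if labels[cfg] >= 0:
            continue
        orbit = set()
        for p in perms:
            new = 0
            for bit in range(8):
                if cfg >> bit & 1:
                    new |= 1 << p[bit]
            orbit.add(new)
        for member in orbit:
            labels[member] = cfg
    return labels


def _expand() -> np.ndarray:
    labels = _orbit_labels()
    weights = np.zeros(256)
    for rep, value in _CLASS_WEIGHTS.items():
        weights[labels == labels[rep]] = value
    return weights


SURFACE_CONFIG_WEIGHTS = _expand()
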