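"""Rasterisation of simple solids onto anisotropic voxel grids.

A voxel with index ``(z, y, x)`` on a grid with spacing ``(dz, dy, dx)`` has
its centre at ``((z+0.5)dz, (y+0.5)dy, (x+0.5)dx)``; a voxel belongs to a
solid when its centre does.  These digitisations serve as ground truth for
the morphology pipeline and as calibration bodies for the surface-area
estimator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["digital_sphere", "digital_box", "digital_tube", "coords_to_mask", "mask_to_coords"]


def _centre_grid(shape, spacing):
    dz, dy, dx = spacing
    z, y, x = np.indices(shape)
    return (z + 0.5) * dz, (y + 0.5) * dy, (x + 0.5) * dx


def digital_sphere(
    radius: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    centre: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Voxel indices (n, 3) of a ball of physical ``radius`` (same units as spacing).

    ``centre`` is a physical coordinate; by default the ball is centred
    slightly off the voxel lattice so that digitisation artefacts are not
    aligned with symmetry planes.
    """
    dz, dy, dx = spacing
    nz = int(np.ceil(2 * radius / dz)) + 3
    ny = int(np.ceil(2 * radius / dy)) + 3
    nx = int(np.ceil(2 * radius / dx)) + 3
    if centre is None:
        centre = (nz * dz / 2 + 0.17 * dz, ny * dy / 2 + 0.23 * dy, nx * dx / 2 + 0.11 * dx)
    cz, cy, cx = centre
    z, y, x = _centre_grid((nz, ny, nx), spacing)
    inside = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
    return np.argwhere(inside)


def digital_box(extent_vox: tuple[int, int, int]) -> np.ndarray:
    """Voxel indices of a filled axis-aligned box of the given voxel extent."""
    return np.argwhere(np.ones(extent_vox, dtype=bool))


def digital_tube(
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    radius: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Voxel indices of a capsule (cylinder with hemispherical caps).

    ``start``/``end`` are physical coordinates of the axis endpoints; voxels
    whose centre lies within ``radius`` of the segment are included.  Only
    voxels inside ``shape`` are returned.
    """
    z, y, x = _centre_grid(shape, spacing)
    p = np.stack([z, y, x], axis=-1)
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        t = np.zeros(shape)
    else:
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., np.newaxis] * ab
    inside = ((p - closest) ** 2).sum(axis=-1) <= radius**2
    return np.argwhere(inside)


def coords_to_mask(coords: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean volume with True at each (z, y, x) row of ``coords``."""
    m = np.zeros(shape, dtype=bool)
    coords = np.asarray(coords)
    if coords.size:
        m[tuple(coords.T)] = True
    return m


def mask_to_coords(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(mask)
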