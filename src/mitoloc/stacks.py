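"""Multi-channel 3D image stacks, per-cell ROIs and binary masks.

Conventions used throughout the package:

* voxel indices are 0-based ``(z, y, x)``;
* ROIs are axis-aligned boxes with half-open bounds ``[lo, hi)``;
* voxel spacing is ``(dz, dy, dx)`` in micrometres and may be anisotropic
  (``dz`` typically exceeds ``dx = dy`` on commercial microscopes);
* physical coordinates use the voxel-centre convention: the centre of the
  voxel with index ``i`` along an axis with spacing ``s`` sits at ``(i + 0.5) * s``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "CellROI",
    "BinaryVolume",
    "read_stack",
    "write_stack",
    "crop_cell",
    "read_rois",
    "write_rois",
    "write_mask",
]

#: intensity ceiling that 32-bit float/int inputs are rescaled onto before
#: histogram-based thresholding (16-bit camera range)
U16_MAX = 65535.0


@dataclass
class ImageStack:
    """A 3D (z, y, x) or 4D (channel, z, y, x) non-negative intensity grid.

    Parameters
    ----------
    voxels
        Intensity array.  A 3D array is treated as a single unnamed channel.
    spacing
        ``(dz, dy, dx)`` voxel spacing in micrometres, all strictly positive.
    channel_names
        Ordered channel labels, e.g. ``("gfp", "mcherry")``.  Length must
        match the channel axis (1 for a 3D array).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: tuple[str, ...] = ("channel0",)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[np.newaxis]
            if len(self.channel_names) != 1:
                raise ValueError("3D stack must declare exactly one channel name")
        if self.voxels.ndim != 4:
            raise ValueError(f"expected 3D or 4D voxel array, got ndim={self.voxels.ndim}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if not 1 <= self.voxels.shape[0] <= 3:
            raise ValueError("channel count must be 1, 2 or 3")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values (dz, dy, dx)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial (z, y, x) shape."""
        return self.voxels.shape[1:]

    def channel(self, name: str | int) -> np.ndarray:
        """Return one channel's 3D volume by name or position."""
        if isinstance(name, int):
            return self.voxels[name]
        try:
            return self.voxels[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None


@dataclass(frozen=True)
class CellROI:
    """Axis-aligned box selecting one cell: 0-based, half-open ``[lo, hi)``."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    label: str = "cell"

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"ROI {self.label!r} has empty interior: {self.lo}..{self.hi}")
        if any(l < 0 for l in self.lo):
            raise ValueError(f"ROI {self.label!r} has negative bounds")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def compose(self, inner: "CellROI") -> "CellROI":
        """ROI equivalent to cropping by ``self`` then by ``inner``."""
        lo = tuple(a + b for a, b in zip(self.lo, inner.lo))
        hi = tuple(a + b for a, b in zip(self.lo, inner.hi))
        return CellROI(lo, hi, inner.label)


@dataclass
class BinaryVolume:
    """A boolean 3D mask plus the spacing and provenance of its thresholding."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float],
    channel_names: Sequence[str] = ("gfp", "mcherry"),
) -> ImageStack:
    """Read a TIFF z-stack (single- or multi-channel) into an :class:`ImageStack`.

    Spacing is user-supplied metadata (it is rarely stored reliably in the
    files produced by acquisition software).  32-bit data — as written by
    structured-illumination reconstruction — are linearly rescaled so the
    volume maximum maps to the 16-bit ceiling, which keeps histogram-based
    thresholding on a common footing with native 16-bit acquisitions.

    The TIFF may be laid out as (z, y, x), (c, z, y, x) or (z, c, y, x);
    the channel axis is identified as the axis whose length equals
    ``len(channel_names)`` (checked in that order).
    """
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    n_ch = len(channel_names)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim == 3:
        if n_ch != 1:
            raise ValueError(
                f"file {path} holds a single-channel stack but {n_ch} channel names given"
            )
        arr = arr[np.newaxis]
    elif arr.ndim == 4:
        if arr.shape[0] == n_ch:
            pass
        elif arr.shape[1] == n_ch:
            arr = np.moveaxis(arr, 1, 0)
        else:
            raise ValueError(
                f"file {path}: no axis of length {n_ch} matching the declared channels "
                f"in shape {arr.shape}"
            )
    else:
        raise ValueError(f"file {path}: unsupported TIFF dimensionality {arr.ndim}")

    arr = arr.astype(np.float64)
    if np.dtype(tifffile.imread(str(path)).dtype).itemsize >= 4:
        peak = arr.max()
        if peak > 0:
            arr = arr * (U16_MAX / peak)
    return ImageStack(arr, spacing, tuple(channel_names))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write the stack as a (c, z, y, x) 16-bit TIFF (clipped to range)."""
    data = np.clip(np.rint(stack.voxels), 0, U16_MAX).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def write_mask(vol: BinaryVolume, path: str | Path) -> None:
    """Write a binary mask as 8-bit TIFF (255 = foreground)."""
    tifffile.imwrite(str(path), (vol.mask.astype(np.uint8) * 255), photometric="minisblack")


def full_extent_roi(stack: ImageStack, label: str = "cell") -> CellROI:
    """ROI spanning the whole stack (for pre-cropped single-cell images)."""
    return CellROI((0, 0, 0), stack.shape, label)


def crop_cell(stack: ImageStack, roi: CellROI) -> ImageStack:
    """Extract the sub-stack covered by ``roi``; spacing is preserved."""
    shape = stack.shape
    if any(h > s for h, s in zip(roi.hi, shape)):
        raise ValueError(f"ROI {roi.label!r} {roi.lo}..{roi.hi} exceeds stack extent {shape}")
    sub = stack.voxels[(slice(None),) + roi.slices()].copy()
    return replace(stack, voxels=sub)


# --- ROI sidecar -------------------------------------------------------------
# CSV columns: label, z0, y0, x0, z1, y1, x1 (half-open upper bounds).
# A JSON sidecar holds a list of {"label": ..., "lo": [z,y,x], "hi": [z,y,x]}.

_ROI_FIELDS = ["label", "z0", "y0", "x0", "z1", "y1", "x1"]


def write_rois(rois: Sequence[CellROI], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [{"label": r.label, "lo": list(r.lo), "hi": list(r.hi)} for r in rois]
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ROI_FIELDS)
        for r in rois:
            w.writerow([r.label, *r.lo, *r.hi])


def read_rois(path: str | Path) -> list[CellROI]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return [CellROI(tuple(e["lo"]), tuple(e["hi"]), str(e["label"])) for e in payload]
    out: list[CellROI] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lo = (int(row["z0"]), int(row["y0"]), int(row["x0"]))
            hi = (int(row["z1"]), int(row["y1"]), int(row["x1"]))
            out.append(CellROI(lo, hi, row["label"]))
    return out
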