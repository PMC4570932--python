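"""Ground-truthed synthetic dual-channel stacks of mitochondria-like scenes.

Scenes emulate the package's real inputs: a dark field holding one yeast-like
cell whose mitochondria are tubes and spheres, imaged in two channels on an
anisotropic grid (z spacing coarser than xy).  The green channel carries the
structure marker on the objects; in the red channel a controllable fraction
``phi`` of the marker is delocalised from the objects into an ellipsoidal
cytosol, emulating the loss of membrane potential up to a fully cytosolic
distribution at ``phi = 1``.  Optics and detection are modelled as a Gaussian
point-spread blur followed by Poisson shot noise and Gaussian read noise.
Every scene is generated from an explicit seed; identical specs produce
byte-identical stacks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import coords_to_mask, digital_tube
from .stacks import CellROI, ImageStack, full_extent_roi

__all__ = [
    "SphereSpec",
    "TubeSpec",
    "SceneSpec",
    "rasterise",
    "plan_vs_partition",
    "make_fragmentation_series",
    "make_delocalisation_series",
    "encode_ground_truth",
    "decode_ground_truth",
]

# defaults emulating widefield acquisition of a single yeast cell:
# 200 nm z sections, 100 nm pixels, ~5.6 um field
DEFAULT_SHAPE = (28, 56, 56)
DEFAULT_SPACING = (0.2, 0.1, 0.1)
DEFAULT_FOREGROUND = 1000.0
DEFAULT_BACKGROUND = 20.0
#: Gaussian read noise as a fraction of the foreground level
DEFAULT_READ_NOISE_FRACTION = 0.02
#: in-plane PSF width in pixels (z width scaled by dx/dz)
DEFAULT_PSF_SIGMA = 1.0
#: total mitochondrial volume per synthetic cell, um^3
DEFAULT_TOTAL_VOLUME = 2.0
#: minimum clearance between object surfaces, um (keeps objects separable
#: after PSF blur)
PLACEMENT_GAP = 0.35


@dataclass(frozen=True)
class SphereSpec:
    centre: tuple[float, float, float]  # (z, y, x) um
    radius: float  # um

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class TubeSpec:
    """Capsule chain along a polyline of (z, y, x) physical points."""

    points: tuple[tuple[float, float, float], ...]
    radius: float  # um

    def length(self) -> float:
        p = np.asarray(self.points)
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    def volume(self) -> float:
        # capsule: cylinder body plus hemispherical caps
        r = self.radius
        return math.pi * r**2 * self.length() + 4.0 / 3.0 * math.pi * r**3


@dataclass
class SceneSpec:
    objects: list
    red_delocalised_fraction: float = 0.0
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    foreground: float = DEFAULT_FOREGROUND
    background: float = DEFAULT_BACKGROUND
    #: photons per intensity unit for shot noise; 0 disables the Poisson term
    poisson_scale: float = 1.0
    read_noise_fraction: float = DEFAULT_READ_NOISE_FRACTION
    psf_sigma: float = DEFAULT_PSF_SIGMA
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.red_delocalised_fraction <= 1.0:
            raise ValueError("red_delocalised_fraction must lie in [0, 1]")
        for o in self.objects:
            if o.radius <= 0:
                raise ValueError("object radii must be positive")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["objects"] = [
            {"type": type(o).__name__, **asdict(o)} for o in self.objects
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneSpec":
        payload = json.loads(Path(path).read_text())
        objs = []
        for o in payload.pop("objects"):
            kind = o.pop("type", None)
            if kind == "SphereSpec":
                objs.append(SphereSpec(tuple(o["centre"]), float(o["radius"])))
            elif kind == "TubeSpec":
                objs.append(TubeSpec(tuple(tuple(p) for p in o["points"]), float(o["radius"])))
            else:
                raise ValueError(f"unknown object type {kind!r} in scene spec")
        for key in ("shape", "spacing"):
            payload[key] = tuple(payload[key])
        return cls(objects=objs, **payload)


def _cytosol_mask(shape, spacing) -> np.ndarray:
    """Ellipsoidal cell body filling ~90% of the field in each axis."""
    z, y, x = np.indices(shape).astype(np.float64)
    dz, dy, dx = spacing
    cz, cy, cx = (np.array(shape) * spacing) / 2.0
    az, ay, ax = 0.45 * np.array(shape) * spacing
    return (
        (((z + 0.5) * dz - cz) / az) ** 2
        + (((y + 0.5) * dy - cy) / ay) ** 2
        + (((x + 0.5) * dx - cx) / ax) ** 2
    ) <= 1.0


def _rasterise_object(obj, shape, spacing) -> np.ndarray:
    if isinstance(obj, SphereSpec):
        # a zero-length capsule is a ball, rasterised on the scene grid
        coords = digital_tube(obj.centre, obj.centre, obj.radius, shape, spacing)
        return coords_to_mask(coords, shape)
    if isinstance(obj, TubeSpec):
        m = np.zeros(shape, dtype=bool)
        pts = obj.points
        for a, b in zip(pts[:-1], pts[1:]):
            m |= coords_to_mask(digital_tube(a, b, obj.radius, shape, spacing), shape)
        return m
    raise TypeError(f"unsupported object {type(obj).__name__}")


def rasterise(spec: SceneSpec) -> tuple[ImageStack, list[np.ndarray]]:
    """Render a scene into a (gfp, mcherry) stack plus pre-blur ground truth.

    Ground truth is the list of 26-connected components of the union of the
    rasterised objects (overlapping objects merge into one component).
    """
    mito = np.zeros(spec.shape, dtype=bool)
    for obj in spec.objects:
        mito |= _rasterise_object(obj, spec.shape, spec.spacing)
    labels, n = ndimage.label(mito, structure=np.ones((3, 3, 3), dtype=bool))
    truth = [np.argwhere(labels == i) for i in range(1, n + 1)]

    cyt = _cytosol_mask(spec.shape, spec.spacing) | mito
    phi = spec.red_delocalised_fraction
    fg, bg = spec.foreground, spec.background

    green = np.full(spec.shape, bg, dtype=np.float64)
    green[mito] += fg
    red = np.full(spec.shape, bg, dtype=np.float64)
    red[mito] += (1.0 - phi) * fg
    if mito.any() and cyt.any():
        # delocalised share conserves integrated signal over the cell body
        red[cyt] += phi * fg * mito.sum() / cyt.sum()

    dz, dy, dx = spec.spacing
    if spec.psf_sigma > 0:
        sig = (spec.psf_sigma * dx / dz, spec.psf_sigma, spec.psf_sigma)
        green = ndimage.gaussian_filter(green, sig)
        red = ndimage.gaussian_filter(red, sig)

    rng = np.random.default_rng(spec.rng_seed)
    read_sigma = spec.read_noise_fraction * fg
    channels = []
    for clean in (green, red):
        if spec.poisson_scale > 0:
            noisy = rng.poisson(clean * spec.poisson_scale) / spec.poisson_scale
        else:
            noisy = clean.copy()
        if read_sigma > 0:
            noisy += rng.normal(0.0, read_sigma, size=clean.shape)
        channels.append(np.clip(noisy, 0.0, None))
    stack = ImageStack(np.stack(channels), spec.spacing, ("gfp", "mcherry"))
    return stack, truth


# --- fragmentation series ----------------------------------------------------


def plan_vs_partition(
    target_f: float,
    rng: np.random.Generator,
    threshold: float = 20.0,
    frag_nominal: float = 11.0,
    frag_max: float = 14.0,
    min_part: float = 5.0,
) -> list[float]:
    """Analytic relative-volume partition realising a fragmentation index.

    Fragment parts are kept at or below ``frag_max`` — comfortably under the
    classification ``threshold`` — so that measurement noise on relative
    volumes cannot flip a designed fragment across the threshold.  The
    non-fragment remainder (if any) is a single object above the threshold.

    Raises
    ------
    ValueError
        If the target is infeasible: a remainder that would itself fall at or
        below the threshold, or a fragment below ``min_part`` (which could be
        lost to the small-volume artefact filter).
    """
    if not 0.0 <= target_f <= 100.0:
        raise ValueError("target_f must lie in [0, 100]")
    if target_f == 0.0:
        return [100.0]
    parts: list[float] = []
    if target_f < 100.0:
        remainder = 100.0 - target_f
        if remainder <= threshold:
            raise ValueError(
                f"infeasible target f={target_f}: remainder {remainder} would itself "
                f"count as a fragment (threshold {threshold})"
            )
        parts.append(remainder)
    if target_f < min_part:
        raise ValueError(f"target f={target_f} needs a fragment below {min_part}%")
    k = max(1, math.ceil(target_f / frag_nominal))
    frag = np.full(k, target_f / k)
    if k > 1:
        jitter = rng.uniform(0.85, 1.15, size=k)
        frag = frag * jitter
        frag *= target_f / frag.sum()
    if np.any(frag > frag_max) or np.any(frag < min_part):
        frag = np.full(k, target_f / k)  # fall back to even split
    return parts + [float(v) for v in frag]


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments p1-q1 and p2-q2."""
    p1, q1, p2, q2 = (np.asarray(v, dtype=np.float64) for v in (p1, q1, p2, q2))
    # dense sampling is robust and fast enough for placement checks
    t = np.linspace(0.0, 1.0, 25)
    a = p1[None, :] + t[:, None] * (q1 - p1)
    b = p2[None, :] + t[:, None] * (q2 - p2)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


class _Placer:
    """Rejection-sampling placement of non-overlapping objects in the cell."""

    def __init__(self, shape, spacing, rng, gap: float = PLACEMENT_GAP):
        self.extent = np.array(shape) * np.array(spacing)
        self.centre = self.extent / 2.0
        self.semi = 0.42 * self.extent
        self.rng = rng
        self.gap = gap
        self.placed: list[tuple[np.ndarray, np.ndarray, float]] = []  # (a, b, radius)

    def _inside(self, p, margin) -> bool:
        return float((((p - self.centre) / (self.semi - margin)) ** 2).sum()) <= 1.0

    def _clear(self, a, b, radius) -> bool:
        for pa, pb, pr in self.placed:
            if _segment_distance(a, b, pa, pb) < radius + pr + self.gap:
                return False
        return True

    def place_sphere(self, radius: float, tries: int = 400) -> SphereSpec:
        for _ in range(tries):
            p = self.centre + self.rng.uniform(-1, 1, 3) * (self.semi - radius)
            if self._inside(p, radius) and self._clear(p, p, radius):
                self.placed.append((p, p, radius))
                return SphereSpec(tuple(p), radius)
        raise RuntimeError("could not place sphere without overlap")

    def place_tube(self, length: float, radius: float, tries: int = 400) -> TubeSpec:
        max_seg = 0.8 * float(self.semi.min())
        n_seg = max(1, math.ceil(length / max_seg))
        seg_len = length / n_seg
        for _ in range(tries):
            pts = [self.centre + self.rng.uniform(-1, 1, 3) * (self.semi - radius)]
            ok = self._inside(pts[0], radius)
            for _ in range(n_seg):
                if not ok:
                    break
                for _ in range(40):
                    u = self.rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    nxt = pts[-1] + u * seg_len
                    if self._inside(nxt, radius):
                        pts.append(nxt)
                        break
                else:
                    ok = False
            if not ok or len(pts) != n_seg + 1:
                continue
            segs = list(zip(pts[:-1], pts[1:]))
            if all(self._clear(a, b, radius) for a, b in segs):
                for a, b in segs:
                    self.placed.append((np.asarray(a), np.asarray(b), radius))
                return TubeSpec(tuple(tuple(p) for p in pts), radius)
        raise RuntimeError("could not place tube without overlap")


def _sphere_radius(volume: float) -> float:
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def _tube_for_volume(volume: float, radius: float) -> float:
    """Axis length of a capsule of given radius and volume (>= 0)."""
    caps = 4.0 / 3.0 * math.pi * radius**3
    if volume <= caps:
        raise ValueError(f"volume {volume} too small for tube radius {radius}")
    return (volume - caps) / (math.pi * radius**2)


def build_cell_scene(
    vs_parts: list[float],
    style: str,
    rng_seed: int,
    total_volume: float = DEFAULT_TOTAL_VOLUME,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    red_delocalised_fraction: float = 0.0,
    **scene_kwargs,
) -> SceneSpec:
    """Realise a relative-volume partition as placed solids of one style.

    ``style`` is ``"spherical"`` (all objects balls, as after oxidative
    fragmentation) or ``"tubular"`` (all objects capsules, as in
    respiration-deficient cells).  Large parts are placed first.
    """
    if style not in ("spherical", "tubular"):
        raise ValueError(f"style must be 'spherical' or 'tubular', got {style!r}")
    rng = np.random.default_rng(rng_seed)
    placer = _Placer(shape, spacing, rng)
    objects = []
    for part in sorted(vs_parts, reverse=True):
        vol = part / 100.0 * total_volume
        if style == "spherical":
            objects.append(placer.place_sphere(_sphere_radius(vol)))
        else:
            # thicker tubes for the large network piece keep lengths placeable
            radius = 0.30 if part > 20.0 else 0.18
            length = _tube_for_volume(vol, radius)
            objects.append(placer.place_tube(length, radius))
    return SceneSpec(
        objects=objects,
        red_delocalised_fraction=red_delocalised_fraction,
        shape=shape,
        spacing=spacing,
        rng_seed=rng_seed,
        **scene_kwargs,
    )


def make_fragmentation_series(
    style: str,
    target_f: float,
    n_cells: int,
    rng_seed: int,
    **scene_kwargs,
) -> list[tuple[ImageStack, float]]:
    """Cells whose ground-truth relative volumes realise ``target_f`` exactly.

    Returns one ``(stack, expected_f)`` pair per cell; the expected index is
    the designed one (the sum of the planned fragment parts), the stacks are
    rendered with per-cell seeds derived deterministically from ``rng_seed``.
    """
    ss = np.random.SeedSequence(rng_seed)
    out = []
    for i, child in enumerate(ss.spawn(n_cells)):
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(seed)
        parts = plan_vs_partition(target_f, rng)
        expected_f = float(sum(p for p in parts if p <= 20.0))
        spec = build_cell_scene(parts, style, rng_seed=seed, **scene_kwargs)
        stack, _ = rasterise(spec)
        out.append((stack, expected_f))
    return out


def make_delocalisation_series(
    phis: list[float],
    n_cells: int,
    rng_seed: int,
    **scene_kwargs,
) -> dict[float, list[ImageStack]]:
    """Groups of identical-morphology cells differing only in ``phi``.

    Every ``phi`` group reuses the same per-cell geometry seeds so that the
    comparison across delocalised fractions is paired, mirroring a time
    course of uncoupler treatment.
    """
    ss = np.random.SeedSequence(rng_seed)
    cell_seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_cells)]
    out: dict[float, list[ImageStack]] = {}
    for phi in phis:
        stacks = []
        for seed in cell_seeds:
            rng = np.random.default_rng(seed)
            parts = plan_vs_partition(30.0, rng)
            spec = build_cell_scene(
                parts, "tubular", rng_seed=seed, red_delocalised_fraction=phi, **scene_kwargs
            )
            stack, _ = rasterise(spec)
            stacks.append(stack)
        out[phi] = stacks
    return out


def full_roi(stack: ImageStack, label: str = "cell") -> CellROI:
    """ROI spanning the whole (already cropped) stack."""
    return full_extent_roi(stack, label)


# --- ground-truth serialisation ---------------------------------------------


def encode_ground_truth(truth: list[np.ndarray], shape: tuple[int, int, int]) -> dict:
    """Run-length encode component voxel sets over the flattened (z,y,x) grid."""
    ny, nx = shape[1], shape[2]
    comps = []
    for coords in truth:
        flat = np.sort(coords[:, 0] * ny * nx + coords[:, 1] * nx + coords[:, 2])
        runs = []
        start = prev = int(flat[0])
        for v in flat[1:]:
            v = int(v)
            if v == prev + 1:
                prev = v
                continue
            runs.append([start, prev - start + 1])
            start = prev = v
        runs.append([start, prev - start + 1])
        comps.append(runs)
    return {"shape": list(shape), "components_rle": comps}


def decode_ground_truth(payload: dict) -> list[np.ndarray]:
    shape = tuple(payload["shape"])
    ny, nx = shape[1], shape[2]
    out = []
    for runs in payload["components_rle"]:
        flat = np.concatenate([np.arange(s, s + ln) for s, ln in runs])
        z, rem = np.divmod(flat, ny * nx)
        y, x = np.divmod(rem, nx)
        out.append(np.stack([z, y, x], axis=1))
    return out
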