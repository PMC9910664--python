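"""Synthetic mouse-thorax and calibration phantoms with voxel-level truth.

No public scan data accompany the segmentation task list, so validation
runs on phantoms that emulate the intensity ordering the thresholds rely
on: air background, a soft-tissue body, two low-intensity lung fields
containing bright vessel trees and denser disease lesions, a conducting
airway joining the lungs, and a medial-ventral heart, plus additive
Gaussian noise.  Default intensities sit well clear of the 55 threshold on
both sides so tests probe the pipeline rather than threshold luck.

Geometry notes (all lengths scale with the volume shape):

* the two lung ellipsoids are separated by more than twice the default
  per-slice closing radius, so closing the aerated ROI fills intra-lung
  holes without bridging the mediastinum at this desk-scale field of view;
* the airway (trachea + mainstem bronchi) crosses the midline *above* the
  lung fields and plunges into the apices, keeping the two lungs one
  connected air space while coexisting with lung cross-sections in as few
  slices as possible;
* the heart sits ventral and caudal of the airway, outside the aerated
  region, mirroring the ventral mediastinum;
* lesions grow as spherical blobs around a fixed set of focal centres, so
  raising the lesion volume fraction makes lesions coalesce (consolidation)
  instead of scattering new small structures; at a fixed seed the lesion
  masks are nested across fractions.

One seeded generator per phantom, split into three named streams consumed
in a fixed order (vessels, lesions, noise), gives bit-reproducible volumes;
the noise field is identical across lesion fractions at a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io_volumes
from .containers import BinaryMask, VolumeImage
from .errors import PatsError

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_thorax_phantom",
    "generate_calibration_phantom",
    "save_phantom",
]

DEFAULT_INTENSITIES = {
    "background_air": 20,
    "body_tissue": 120,
    "lung_parenchyma": 35,
    "vessel": 130,
    "lesion": 110,
    "heart": 125,
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic thorax.

    ``lesion_volume_fraction`` is the target lesion volume as a fraction of
    the lung-field volume (0.2 by default: a moderate, fibrosis-peak-like
    burden).  ``vessel_depth`` and ``vessel_trunk_radius_frac`` control the
    recursive vessel tree; the defaults model the arterial generations
    actually resolvable at the 35 um in vivo voxel size (trunk radius
    0.043 of the x extent, 11 px = 0.39 mm, down to ~6 px = 215 um over
    three generations) -- finer vessels are below in-plane resolution and
    are not part of the stated truth.
    """

    shape: tuple[int, int, int] = (200, 256, 256)
    voxel_size_um: float = 35.0
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 6.0
    lesion_volume_fraction: float = 0.2
    vessel_depth: int = 3
    vessel_trunk_radius_frac: float = 0.043
    seed: int = 42

    def __post_init__(self) -> None:
        it = self.intensities
        for k, v in it.items():
            if not (0 <= v <= 255):
                raise PatsError(f"intensity {k}={v} outside [0, 255]")
        for k in ("background_air", "lung_parenchyma"):
            if it[k] > 55:
                raise PatsError(f"{k} intensity must be <= 55 (air threshold)")
        for k in ("body_tissue", "vessel", "lesion", "heart"):
            if it[k] < 55:
                raise PatsError(f"{k} intensity must be >= 55 (tissue threshold)")
        if not (0.0 <= self.lesion_volume_fraction <= 0.5):
            raise PatsError("lesion_volume_fraction must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise PatsError("noise_sd must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        return json.dumps(d, indent=2)


@dataclass
class PhantomTruth:
    """A phantom volume with its labelled ground-truth masks."""

    volume: VolumeImage
    masks: dict[str, BinaryMask]
    spec: PhantomSpec | dict


# ---------------------------------------------------------------------------
# geometric primitives (all on (z, y, x) index grids)


def _ellipsoid(shape, center, semi) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    lo = [max(0, int(np.floor(c - s))) for c, s in zip(center, semi)]
    hi = [min(n, int(np.ceil(c + s)) + 1) for n, c, s in zip(shape, center, semi)]
    if any(l >= h for l, h in zip(lo, hi)):
        return out
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    val = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = val <= 1.0
    return out


def _ball(shape, center, radius) -> np.ndarray:
    return _ellipsoid(shape, center, (radius, radius, radius))


def _capsule(shape, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (a cylinder with round caps)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    out = np.zeros(shape, dtype=bool)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return out
    grids = np.meshgrid(
        *[np.arange(l, h, dtype=float) for l, h in zip(lo, hi)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        dist2 = ((pts - p0) ** 2).sum(axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = ((pts - proj) ** 2).sum(axis=-1)
    out[tuple(slice(l, h) for l, h in zip(lo, hi))] = dist2 <= radius * radius
    return out


def _vessel_tree(
    shape,
    rng: np.random.Generator,
    start,
    direction,
    radius: float,
    length: float,
    depth: int,
    min_radius: float = 5.0,
) -> np.ndarray:
    """Recursive bifurcating tube tree; deterministic depth-first rng order."""
    mask = np.zeros(shape, dtype=bool)
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)

    def grow(p0, dirv, r, ln, level):
        nonlocal mask
        if level > depth or r < min_radius:
            return
        p1 = np.asarray(p0) + dirv * ln
        mask |= _capsule(shape, p0, p1, r)
        for _ in range(2):
            # tilt the child direction by a random angle in a random plane
            rand = rng.standard_normal(3)
            perp = rand - (rand @ dirv) * dirv
            n = np.linalg.norm(perp)
            perp = perp / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
            ang = np.deg2rad(rng.uniform(15.0, 35.0))
            child = np.cos(ang) * dirv + np.sin(ang) * perp
            child /= np.linalg.norm(child)
            grow(p1, child, r * 0.75, ln * 0.75, level + 1)

    grow(np.asarray(start, dtype=float), direction, radius, length, 1)
    return mask


# ---------------------------------------------------------------------------


def _thorax_geometry(shape) -> dict:
    """Shared thorax layout, all lengths proportional to the volume shape.

    Three hard constraints at the default 256-px field of view:

    * the chest wall encloses the lung fields in every slice (air may not
      breach the body surface, or the shrink-wrap flood fill leaks in);
    * the inter-lung gap at the equators (84/256 of the x extent) exceeds
      twice the default closing radius, so the per-slice closing of the
      aerated ROI cannot bridge the mediastinum;
    * the lungs stay more than the default closing radius away from the
      volume border: with the fixed border contract (foreground padding
      for erosion) a closing whose dilation clips at the border would
      otherwise bulge to the edge of the field of view.
    """
    nz, ny, nx = shape
    return {
        "body_center": (0.5 * nz, 0.5 * ny, 0.5 * nx),
        "body_semi": (0.48 * nz, 0.44 * ny, 0.46 * nx),
        "lung_cx": (0.5 * nx - 0.242 * nx, 0.5 * nx + 0.242 * nx),
        "lung_center_zy": (0.50 * nz, 0.44 * ny),
        "lung_semi": (0.30 * nz, 0.19 * ny, 0.078 * nx),
        "heart_center": (0.45 * nz, 0.64 * ny, 0.5 * nx),
        "heart_semi": (0.14 * nz, 0.10 * ny, 0.078 * nx),
    }


def generate_thorax_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Build the synthetic thorax and its ground-truth masks.

    Deterministic for a fixed seed.  Raises ``"lesion packing failed"``
    when the requested lesion fraction cannot be placed.
    """
    spec = spec or PhantomSpec()
    nz, ny, nx = spec.shape
    it = spec.intensities
    geo = _thorax_geometry(spec.shape)
    ss = np.random.SeedSequence(spec.seed)
    rng_vessels, rng_lesions, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    body = _ellipsoid(spec.shape, geo["body_center"], geo["body_semi"])
    lung_cx = geo["lung_cx"]
    lungs = np.zeros(spec.shape, dtype=bool)
    for cx in lung_cx:
        lungs |= _ellipsoid(spec.shape, (*geo["lung_center_zy"], cx),
                            geo["lung_semi"])

    # conducting airway: trachea down to a carina above the lung fields,
    # horizontal mainstem bronchi, then near-vertical entry into each apex
    r_tr = max(2.0, 0.020 * nx)
    r_br = max(2.0, 0.0176 * nx)
    ay = 0.39 * ny
    carina = (0.155 * nz, ay, 0.5 * nx)
    airway = _capsule(spec.shape, (0.06 * nz, ay, 0.5 * nx), carina, r_tr)
    for cx in lung_cx:
        elbow = (0.165 * nz, ay, cx)
        airway |= _capsule(spec.shape, carina, elbow, r_br)
        airway |= _capsule(
            spec.shape, elbow, (0.26 * nz, 0.42 * ny, cx), r_br
        )
    airway &= body
    airway_guard = ndimage.binary_dilation(
        airway, structure=ndimage.generate_binary_structure(3, 1), iterations=2
    )

    heart = _ellipsoid(spec.shape, geo["heart_center"], geo["heart_semi"])
    heart &= body & ~lungs & ~airway_guard

    # vessel trees, one per lung, rooted near the bronchial entry
    vessels = np.zeros(spec.shape, dtype=bool)
    trunk_r = max(2.0, spec.vessel_trunk_radius_frac * nx)
    for cx, side in zip(lung_cx, (-1.0, 1.0)):
        start = (0.28 * nz, 0.44 * ny, cx + side * 0.02 * nx)
        # vessels track the airways along the lung long axis (craniocaudal)
        direction = (1.0, 0.12, side * 0.05)
        vessels |= _vessel_tree(
            spec.shape, rng_vessels, start, direction,
            radius=trunk_r, length=0.22 * nz, depth=spec.vessel_depth,
        )
    vessels &= lungs & ~airway_guard

    lesions = _place_lesions(
        spec, rng_lesions, lungs, forbidden=airway_guard | vessels
    )

    # assemble intensities (later labels overwrite earlier ones)
    vol = np.full(spec.shape, it["background_air"], dtype=np.float32)
    vol[body] = it["body_tissue"]
    vol[lungs] = it["lung_parenchyma"]
    vol[airway] = it["background_air"]
    vol[lesions] = it["lesion"]
    vol[vessels] = it["vessel"]
    vol[heart] = it["heart"]
    if spec.noise_sd > 0:
        vol += spec.noise_sd * rng_noise.standard_normal(
            spec.shape, dtype=np.float32
        )
    data = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    lung_air = (lungs | airway) & ~vessels & ~lesions
    body_mask = body & ~lungs & ~airway & ~heart
    vs = spec.voxel_size_um
    masks = {
        "body": BinaryMask(body_mask, vs),
        "lung_air": BinaryMask(lung_air, vs),
        "vessels": BinaryMask(vessels, vs),
        "lesions": BinaryMask(lesions, vs),
        "heart": BinaryMask(heart, vs),
    }
    volume = VolumeImage(data, vs, source=f"thorax phantom seed={spec.seed}")
    return PhantomTruth(volume=volume, masks=masks, spec=spec)


def _place_lesions(
    spec: PhantomSpec,
    rng: np.random.Generator,
    lungs: np.ndarray,
    forbidden: np.ndarray,
) -> np.ndarray:
    """Grow lesion blobs around fixed foci until the target fraction is met.

    The rng draw sequence per iteration is fixed, so at a fixed seed the
    lesion mask for a smaller fraction is a subset of that for a larger one.
    """
    nz, ny, nx = spec.shape
    lesions = np.zeros(spec.shape, dtype=bool)
    lung_voxels = int(lungs.sum())
    target = spec.lesion_volume_fraction * lung_voxels
    if target <= 0:
        return lesions

    geo = _thorax_geometry(spec.shape)
    lung_cx = geo["lung_cx"]
    lung_semi = np.array(geo["lung_semi"])
    lung_center_zy = geo["lung_center_zy"]
    # bronchocentric foci: consolidation grows around the central
    # airways/vessels, so foci sit in the lung core rather than subpleurally
    n_foci = 6
    foci = []
    for i in range(n_foci):
        cx = lung_cx[i % 2]
        # uniform point in a 0.45-scaled lung ellipsoid
        while True:
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u @ u) <= 1.0:
                break
        foci.append(np.array((*lung_center_zy, cx)) + 0.45 * lung_semi * u)

    rlo, rhi = 0.039 * nx, 0.0625 * nx
    jitter = 0.25 * lung_semi
    placed = 0
    for _ in range(4000):
        if placed >= target:
            break
        focus = foci[int(rng.integers(n_foci))]
        center = focus + rng.standard_normal(3) * jitter
        radius = rng.uniform(rlo, rhi)
        remaining = target - placed
        cap = (3.0 * remaining / (4.0 * np.pi)) ** (1.0 / 3.0) + 1.0
        radius = min(radius, cap)
        ball = _ball(spec.shape, center, radius) & lungs & ~forbidden
        lesions |= ball
        placed = int(lesions.sum())
    else:
        raise PatsError("lesion packing failed")
    log.debug("lesions: %d voxels (target %.0f)", placed, target)
    return lesions


# ---------------------------------------------------------------------------
# calibration phantoms


def generate_calibration_phantom(kind: str, **params) -> PhantomTruth:
    """Analytic phantoms with exact truth masks.

    ``sphere(radius)``; ``slab_stack(thickness, gap, axis)``;
    ``rod_grid(radius, pitch)``; ``dried_lung(seed, ...)`` -- a single dried
    lobe (tissue with air pockets and an embedded vessel tree) on an air
    background for the ex vivo path.  All synthetic constructions.
    """
    if kind == "sphere":
        return _sphere_phantom(**params)
    if kind == "slab_stack":
        return _slab_stack_phantom(**params)
    if kind == "rod_grid":
        return _rod_grid_phantom(**params)
    if kind == "dried_lung":
        return _dried_lung_phantom(**params)
    raise PatsError(f"unknown calibration phantom kind {kind!r}")


def _finish(kind, data_fg, shape, voxel_size_um, fg=200, bg=20, extra=None):
    if not data_fg.any():
        raise PatsError("geometry exceeding volume bounds: empty foreground")
    data = np.where(data_fg, np.uint8(fg), np.uint8(bg))
    masks = {"object": BinaryMask(data_fg, voxel_size_um)}
    if extra:
        masks.update(extra)
    return PhantomTruth(
        volume=VolumeImage(data, voxel_size_um, source=f"{kind} phantom"),
        masks=masks,
        spec={"kind": kind, "shape": list(shape), "voxel_size_um": voxel_size_um},
    )


def _sphere_phantom(radius=25, shape=None, voxel_size_um=35.0):
    if shape is None:
        n = int(2 * radius + 9)
        shape = (n, max(n, 8), max(n, 8))
    center = tuple((s - 1) / 2.0 for s in shape)
    if any(radius > (s - 1) / 2.0 for s in shape):
        raise PatsError("geometry exceeding volume bounds")
    return _finish("sphere", _ball(shape, center, radius), shape, voxel_size_um)


def _slab_stack_phantom(thickness=5, gap=15, axis=0, shape=(100, 64, 64),
                        voxel_size_um=1000.0, offset=0):
    period = thickness + gap
    if thickness < 1 or gap < 0 or shape[axis] < period:
        raise PatsError("geometry exceeding volume bounds")
    idx = (np.arange(shape[axis]) - offset) % period < thickness
    fg = np.zeros(shape, dtype=bool)
    sl = [None, None, None]
    sl[axis] = idx
    fg = np.moveaxis(fg, axis, 0)
    fg[idx] = True
    fg = np.moveaxis(fg, 0, axis)
    return _finish("slab_stack", fg, shape, voxel_size_um)


def _rod_grid_phantom(radius=4, pitch=16, shape=(60, 96, 96), voxel_size_um=35.0):
    if 2 * radius >= pitch:
        raise PatsError("geometry exceeding volume bounds: rods overlap")
    nz, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    fg2d = np.zeros((ny, nx), dtype=bool)
    for cy in np.arange(pitch / 2, ny, pitch):
        for cx in np.arange(pitch / 2, nx, pitch):
            fg2d |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    fg = np.broadcast_to(fg2d, shape).copy()
    return _finish("rod_grid", fg, shape, voxel_size_um)


def _dried_lung_phantom(shape=(120, 144, 144), voxel_size_um=9.0, seed=42,
                        pocket_fraction=0.15):
    """A single dried lobe: tissue ellipsoid with air pockets and a vessel
    tree, on an air background (synthetic ex vivo specimen)."""
    nz, ny, nx = shape
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    lobe = _ellipsoid(shape, (0.5 * nz, 0.5 * ny, 0.5 * nx),
                      (0.42 * nz, 0.32 * ny, 0.32 * nx))
    inner = _ellipsoid(shape, (0.5 * nz, 0.5 * ny, 0.5 * nx),
                       (0.36 * nz, 0.26 * ny, 0.26 * nx))
    pockets = np.zeros(shape, dtype=bool)
    target = pocket_fraction * lobe.sum()
    for _ in range(4000):
        if pockets.sum() >= target:
            break
        center = (
            rng.uniform(0.2 * nz, 0.8 * nz),
            rng.uniform(0.25 * ny, 0.75 * ny),
            rng.uniform(0.25 * nx, 0.75 * nx),
        )
        pockets |= _ball(shape, center, rng.uniform(2.0, 5.0)) & inner
    vessels = _vessel_tree(
        shape, rng, (0.2 * nz, 0.5 * ny, 0.5 * nx), (1.0, 0.1, 0.1),
        radius=0.03 * nx, length=0.25 * nz, depth=3, min_radius=2.0,
    ) & lobe
    tissue = lobe & ~pockets | vessels
    it = DEFAULT_INTENSITIES
    data = np.full(shape, it["background_air"], dtype=np.uint8)
    data[tissue] = it["body_tissue"]
    data[vessels] = it["vessel"]
    masks = {
        "tissue": BinaryMask(tissue, voxel_size_um),
        "vessels": BinaryMask(vessels & tissue, voxel_size_um),
    }
    return PhantomTruth(
        volume=VolumeImage(data, voxel_size_um, source="dried_lung phantom"),
        masks=masks,
        spec={"kind": "dried_lung", "shape": list(shape),
              "voxel_size_um": voxel_size_um, "seed": seed},
    )


def save_phantom(truth: PhantomTruth, directory: str | Path) -> Path:
    """Write the phantom as slice stacks: volume, truth masks, and the spec
    as structured text."""
    directory = Path(directory)
    io_volumes.write_volume_stack(truth.volume, directory / "volume", prefix="slice")
    for name, mask in truth.masks.items():
        io_volumes.write_roi_stack(mask, directory / f"truth_{name}", prefix=name)
    spec = truth.spec
    text = spec.to_json() if hasattr(spec, "to_json") else json.dumps(spec, indent=2)
    (directory / "phantom_spec.json").write_text(text + "\n")
    # minimal dataset log so read_slice_stack can resolve the voxel size
    (directory / "volume" / "dataset.log").write_text(
        f"[System]\nImage Pixel Size (um)={truth.volume.voxel_size_um}\n"
    )
    return directory
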