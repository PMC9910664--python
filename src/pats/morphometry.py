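"""3D morphometry of binary masks: volumes, thickness, linear density, meshes.

Reported quantities follow standard microCT nomenclature:

TV
    total volume of the VOI (the analysis region, not its bounding box), mm^3;
BV
    object (foreground) volume inside the VOI, mm^3;
BV/TV
    volume fraction;
St.Th
    structure thickness: the volume-weighted mean, over foreground voxels,
    of the diameter of the largest sphere fully inscribed in the foreground
    that contains the voxel, in mm;
St.Li.Dn
    structure linear density: for each principal axis, axis-parallel test
    lines are cast through the VOI and maximal foreground runs are counted;
    the axis value is (total run count) / (total test-line length inside the
    VOI, mm).  The mean over the three axes is reported, with per-axis
    values, together with a plate-model alternative (BV/TV) / St.Th since
    vendor software does not document which formula it prints.

Thickness uses the distance-transform + sphere-painting method (the
model-independent local-thickness definition): a foreground voxel at
Euclidean distance d from the background lies in an inscribed sphere of
diameter 2d - 1 voxels centred there; spheres are painted largest-first so
each voxel records the largest sphere containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr
from skimage import measure

from .containers import BinaryMask, TriangleMesh
from .errors import PatsError, SegmentationError

log = logging.getLogger(__name__)

__all__ = [
    "MorphometryResult",
    "RoiComparison",
    "object_volume",
    "structure_thickness",
    "structure_linear_density",
    "compute_morphometry",
    "marching_cubes_mesh",
    "mesh_volume",
    "mesh_is_watertight",
    "mesh_component_count",
    "compare_rois",
    "cohort_correlation",
]


@dataclass
class MorphometryResult:
    """Morphometric summary of one analysed ROI, all in physical units."""

    total_volume_mm3: float
    object_volume_mm3: float
    volume_fraction: float
    structure_thickness_mm: float | None = None
    structure_linear_density_per_mm: float | None = None
    axis_linear_densities: dict[str, float] = field(default_factory=dict)
    plate_model_density_per_mm: float | None = None

    def to_dict(self) -> dict:
        d = {
            "TV_mm3": self.total_volume_mm3,
            "BV_mm3": self.object_volume_mm3,
            "BV_TV": self.volume_fraction,
            "StTh_mm": self.structure_thickness_mm,
            "StLiDn_per_mm": self.structure_linear_density_per_mm,
            "StLiDn_plate_per_mm": self.plate_model_density_per_mm,
        }
        for ax, v in self.axis_linear_densities.items():
            d[f"StLiDn_{ax}_per_mm"] = v
        return d


@dataclass
class RoiComparison:
    """Pairwise overlap statistics between two aligned ROIs."""

    volume_a_mm3: float
    volume_b_mm3: float
    dice: float
    jaccard: float


def object_volume(mask: BinaryMask) -> float:
    """Foreground volume in mm^3 (voxel count x voxel volume)."""
    return mask.count() * mask.voxel_size_mm**3


def _local_thickness_vox(data: np.ndarray) -> np.ndarray:
    """Local thickness map in voxel units (0 outside the foreground).

    Sphere painting over integer-quantised inscribed radii, largest first.
    Each distinct radius costs one EDT over the foreground bounding box.
    """
    out = np.zeros(data.shape, dtype=np.float32)
    if not data.any():
        return out
    # the distance map needs the full array: a crop may contain no
    # background at all (a slab spanning the volume) or hide the nearest
    # background voxel of a face-adjacent voxel
    if data.all():
        d_full = ndimage.distance_transform_edt(np.pad(data, 1))[
            (slice(1, -1),) * data.ndim
        ]
    else:
        d_full = ndimage.distance_transform_edt(data)
    # crop to bounding box for the painting loop
    sl = ndimage.find_objects(data.astype(np.int8), max_label=1)[0]
    box = data[sl]
    d = d_full[sl]
    rq = np.round(d).astype(np.int32)
    rq[~box] = 0
    th = np.zeros(box.shape, dtype=np.float32)
    for r in np.unique(rq)[::-1]:
        if r == 0:
            break
        centers = rq == r
        if r == 1:
            cov = centers
        else:
            # voxels within r - 0.5 of any centre with inscribed radius r
            cov = ndimage.distance_transform_edt(~centers) <= r - 0.5
        paint = cov & box & (th == 0)
        th[paint] = 2 * r - 1
    # any stragglers (can happen at quantisation seams): their own sphere
    rem = box & (th == 0)
    th[rem] = (2 * d[rem] - 1).astype(np.float32)
    out[sl] = th
    return out


def structure_thickness(mask: BinaryMask) -> tuple[float, np.ndarray]:
    """Volume-weighted mean local thickness (mm) and the per-voxel map (mm)."""
    if not mask.data.any():
        raise SegmentationError("empty mask")
    th = _local_thickness_vox(mask.data)
    mean_vox = float(th[mask.data].mean())
    return mean_vox * mask.voxel_size_mm, th * mask.voxel_size_mm


def _runs_along_axis(fg: np.ndarray, axis: int) -> int:
    """Number of maximal foreground runs along one axis (all lines)."""
    shifted = np.zeros_like(fg)
    sl_to = [slice(None)] * fg.ndim
    sl_from = [slice(None)] * fg.ndim
    sl_to[axis] = slice(1, None)
    sl_from[axis] = slice(None, -1)
    shifted[tuple(sl_to)] = fg[tuple(sl_from)]
    starts = fg & ~shifted
    return int(starts.sum())


def structure_linear_density(
    mask: BinaryMask,
    voi: BinaryMask | None = None,
    stride: int = 1,
) -> tuple[float, dict[str, float]]:
    """Directed-secant structure linear density (per mm).

    Test lines are every voxel row/column/pillar of the VOI (``stride``
    subsamples them for very large volumes).  For each axis the value is
    the number of maximal foreground runs divided by the total in-VOI test
    line length; runs are broken where a line leaves the VOI.  Returns the
    mean over the three axes and the per-axis values.
    """
    if voi is None:
        voi_data = np.ones(mask.shape, dtype=bool)
    else:
        if voi.shape != mask.shape:
            raise PatsError("voi shape mismatch")
        voi_data = voi.data
    if not voi_data.any():
        raise SegmentationError("empty VOI")
    fg_full = mask.data & voi_data
    axis_names = ("z", "y", "x")
    per_axis: dict[str, float] = {}
    for axis in range(3):
        if stride > 1:
            other = [a for a in range(3) if a != axis]
            idx = [slice(None)] * 3
            for o in other:
                idx[o] = slice(None, None, stride)
            fg = fg_full[tuple(idx)]
            vo = voi_data[tuple(idx)]
        else:
            fg, vo = fg_full, voi_data
        length_mm = vo.sum() * mask.voxel_size_mm
        runs = _runs_along_axis(fg, axis)
        per_axis[axis_names[axis]] = runs / length_mm if length_mm > 0 else 0.0
    return float(np.mean(list(per_axis.values()))), per_axis


def compute_morphometry(
    mask: BinaryMask,
    voi: BinaryMask | None = None,
    additional: bool = True,
    stride: int = 1,
) -> MorphometryResult:
    """Basic (TV, BV, BV/TV) and, if ``additional``, thickness and linear
    density of ``mask`` within ``voi`` (default: the full volume)."""
    vox3 = mask.voxel_size_mm**3
    if voi is None:
        tv = float(np.prod(mask.shape)) * vox3
        obj = mask
    else:
        if voi.shape != mask.shape:
            raise PatsError("voi shape mismatch")
        tv = voi.count() * vox3
        obj = mask.like(mask.data & voi.data)
    bv = obj.count() * vox3
    res = MorphometryResult(
        total_volume_mm3=tv,
        object_volume_mm3=bv,
        volume_fraction=bv / tv if tv > 0 else 0.0,
    )
    if additional and obj.data.any():
        st_th, _ = structure_thickness(obj)
        res.structure_thickness_mm = st_th
        mean_dn, per_axis = structure_linear_density(obj, voi=voi, stride=stride)
        res.structure_linear_density_per_mm = mean_dn
        res.axis_linear_densities = per_axis
        if st_th > 0:
            res.plate_model_density_per_mm = res.volume_fraction / st_th
    return res


def marching_cubes_mesh(mask: BinaryMask, level: float = 0.5) -> TriangleMesh:
    """Closed isosurface of a binary mask via topologically consistent
    marching cubes, with vertices in physical mm.

    The mask is padded by one background voxel so the surface is watertight
    even when objects touch the volume border.
    """
    if not mask.data.any() or mask.data.all():
        raise SegmentationError("no surface")
    s = mask.voxel_size_mm
    padded = np.pad(mask.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=level, spacing=(s, s, s), method="lewiner"
    )
    verts = verts - s  # undo the pad offset
    mesh = TriangleMesh(verts, faces)
    if mesh_volume(mesh) < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def mesh_volume(mesh: TriangleMesh) -> float:
    """Signed enclosed volume by the divergence theorem (mm^3)."""
    tri = mesh.triangles()
    return float(
        np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    )


def _edges(mesh: TriangleMesh) -> np.ndarray:
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    return np.sort(e, axis=1)


def mesh_is_watertight(mesh: TriangleMesh) -> bool:
    """True when every undirected edge is shared by exactly two faces."""
    if mesh.n_faces == 0:
        return False
    e = _edges(mesh)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool((counts == 2).all())


def mesh_component_count(mesh: TriangleMesh) -> int:
    """Number of connected surface components (via shared vertices)."""
    e = _edges(mesh)
    n = len(mesh.vertices)
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    ncomp, labels = connected_components(adj, directed=False)
    used = np.unique(mesh.faces)
    return int(np.unique(labels[used]).size)


def compare_rois(a: BinaryMask, b: BinaryMask) -> RoiComparison:
    """Dice and Jaccard overlap plus the two volumes.

    Two empty masks are defined as identical (Dice = Jaccard = 1), logged.
    """
    if a.shape != b.shape:
        raise PatsError("masks not aligned")
    na, nb = a.count(), b.count()
    inter = int((a.data & b.data).sum())
    union = na + nb - inter
    if na == 0 and nb == 0:
        log.warning("both masks empty; Dice defined as 1")
        dice, jacc = 1.0, 1.0
    else:
        dice = 2.0 * inter / (na + nb)
        jacc = inter / union
    vox3 = a.voxel_size_mm**3
    return RoiComparison(
        volume_a_mm3=na * vox3, volume_b_mm3=nb * vox3, dice=dice, jaccard=jacc
    )


def cohort_correlation(x, y) -> tuple[float, float]:
    """Pearson r and R^2 = r^2 over paired volume lists (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PatsError("paired lists must have equal length")
    if len(x) < 3:
        raise PatsError("need at least 3 pairs")
    r = float(pearsonr(x, y).statistic)
    return r, r * r
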