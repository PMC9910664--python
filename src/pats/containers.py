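"""Shared in-memory containers for microCT volumes, masks and meshes.

Arrays are indexed ``(z, y, x)`` with ``z`` the axial slice index, matching
the slice-stack output of small-animal scanners.  Voxel sizes are isotropic
and carried in micrometres; anisotropic input is rejected rather than
silently resampled because every morphometric formula downstream assumes
isotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import PatsError

log = logging.getLogger(__name__)

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "AcquisitionMeta",
    "TriangleMesh",
    "StructuringElement",
]


@dataclass
class VolumeImage:
    """A 3D grayscale intensity volume with a physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Integer intensities, 8- or 16-bit.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    source : str
        Free-text provenance (directory, phantom spec, ...).
    """

    data: np.ndarray
    voxel_size_um: float
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise PatsError(f"volume must be 3D, got shape {self.data.shape}")
        if self.data.dtype == np.uint8:
            pass
        elif self.data.dtype == np.uint16:
            log.warning(
                "16-bit volume: intensity thresholds are NOT rescaled; "
                "defaults assume 8-bit data"
            )
        else:
            raise PatsError(
                f"volume dtype must be uint8 or uint16, got {self.data.dtype}"
            )
        nz, ny, nx = self.data.shape
        if nz < 2 or ny < 8 or nx < 8:
            raise PatsError(
                f"volume too small: need >=2 slices of >=8x8 pixels, got {self.data.shape}"
            )
        if not np.isscalar(self.voxel_size_um) or not self.voxel_size_um > 0:
            raise PatsError("voxel_size_um must be a positive scalar (isotropic)")
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def bit_depth(self) -> int:
        return 8 if self.data.dtype == np.uint8 else 16

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


@dataclass
class BinaryMask:
    """A 3D boolean grid aligned to a :class:`VolumeImage`.

    Serves as ROI, binary selection, or ground truth.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise PatsError(f"mask must be 3D, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise PatsError("voxel_size_um must be positive")
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        """Foreground volume in cubic millimetres."""
        return self.count() * self.voxel_size_mm**3

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.voxel_size_um)

    def like(self, data: np.ndarray) -> "BinaryMask":
        """A new mask with the same voxel size."""
        return BinaryMask(data, self.voxel_size_um)


@dataclass
class AcquisitionMeta:
    """Acquisition metadata parsed from a scanner dataset log."""

    voxel_size_um: float
    kv: float | None = None
    ua: float | None = None
    rotation_step_deg: float | None = None
    filter: str | None = None

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise PatsError("voxel_size_um must be positive")


@dataclass
class TriangleMesh:
    """A triangle surface mesh in physical coordinates (mm).

    Vertices are ``(z, y, x)`` points in millimetres; faces index into the
    vertex list with right-hand-rule winding (outward normals).  Zero-area
    faces are dropped at construction.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise PatsError("face indices out of range")
        if len(self.faces):
            tri = self.vertices[self.faces]
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            area2 = np.einsum("ij,ij->i", cross, cross)
            keep = area2 > 0
            if not keep.all():
                self.faces = self.faces[keep]

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(n, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]


@dataclass(frozen=True)
class StructuringElement:
    """A flat structuring element for binary morphology.

    ``round`` means the set of pixel centres within Euclidean distance
    ``radius`` of the origin; ``square`` the Chebyshev ball.  ``space``
    selects whether operators act per-slice (2D) or volumetrically (3D).
    Radius 0 is the single-pixel element.
    """

    shape: str = "round"
    radius: int = 1
    space: str = "2D"

    def __post_init__(self) -> None:
        if self.shape not in ("round", "square"):
            raise PatsError(f"unknown element shape {self.shape!r}")
        if self.space not in ("2D", "3D"):
            raise PatsError(f"unknown element space {self.space!r}")
        if self.radius < 0 or int(self.radius) != self.radius:
            raise PatsError("radius must be a non-negative integer")

    def footprint(self) -> np.ndarray:
        """Boolean footprint array (2D or 3D depending on ``space``)."""
        r = int(self.radius)
        ndim = 2 if self.space == "2D" else 3
        if r == 0:
            return np.ones((1,) * ndim, dtype=bool)
        grids = np.indices((2 * r + 1,) * ndim) - r
        if self.shape == "round":
            return (grids**2).sum(axis=0) <= r * r
        return np.ones((2 * r + 1,) * ndim, dtype=bool)
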