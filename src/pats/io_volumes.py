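"""Read/write slice-stack volumes, dataset logs, ROI stacks, reports and meshes.

Reconstructed microCT volumes arrive as directories of 2D grayscale slice
images (BMP by default, TIFF/PNG accepted), ordered lexicographically by
filename.  The physical voxel size comes from an explicit argument or from
the scanner's plain-text dataset log co-located with the slices.

Surface models are written as STL (binary by default).  No STL library is
assumed; binary STL is a fixed 50-byte-per-facet record and is written and
parsed directly.
"""

from __future__ import annotations

import logging
import re
import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .containers import AcquisitionMeta, BinaryMask, TriangleMesh, VolumeImage
from .errors import InputError, PatsError

log = logging.getLogger(__name__)

__all__ = [
    "VolumeImage",
    "AcquisitionMeta",
    "TriangleMesh",
    "read_slice_stack",
    "read_dataset_log",
    "write_volume_stack",
    "write_roi_stack",
    "read_roi_stack",
    "write_mesh_stl",
    "read_mesh_stl",
    "write_morphometry_csv",
]

_SLICE_EXTS = (".bmp", ".tif", ".tiff", ".png")

# Dataset-log keys accepted for each metadata field.  Vendor logs drift
# between versions; unknown keys pass through silently.
_LOG_KEYS = {
    "voxel_size_um": ("image pixel size (um)", "pixel size (um)", "voxel size (um)"),
    "kv": ("source voltage (kv)", "x-ray voltage (kv)"),
    "ua": ("source current (ua)", "x-ray current (ua)"),
    "rotation_step_deg": ("rotation step (deg)",),
    "filter": ("filter",),
}


def _read_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # palette/RGB image: accept only if all channels identical
        if arr.shape[2] in (3, 4) and all(
            np.array_equal(arr[..., 0], arr[..., c]) for c in range(1, 3)
        ):
            arr = arr[..., 0]
        else:
            raise InputError(f"not grayscale: {path.name}")
    if arr.ndim != 2:
        raise InputError(f"not grayscale: {path.name}")
    return arr


def read_slice_stack(
    directory: str | Path,
    pattern: str = "*",
    voxel_size_um: float | None = None,
) -> VolumeImage:
    """Read a directory of 2D grayscale slices into a :class:`VolumeImage`.

    Files matching ``pattern`` (with a recognised image extension) are
    sorted lexicographically into z order.  The voxel size is taken from
    the ``voxel_size_um`` argument, else from a co-located dataset log
    (``*.log``), else an error is raised.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"no such directory: {directory}")
    files = sorted(
        p for p in directory.glob(pattern) if p.suffix.lower() in _SLICE_EXTS
    )
    if len(files) < 2:
        raise InputError(
            f"inconsistent stack: need >=2 slice files, found {len(files)}"
        )
    slices = [_read_slice(p) for p in files]
    shape0, dtype0 = slices[0].shape, slices[0].dtype
    for p, s in zip(files, slices):
        if s.shape != shape0 or s.dtype != dtype0:
            raise InputError(
                f"inconsistent stack: {p.name} has shape {s.shape} ({s.dtype}), "
                f"expected {shape0} ({dtype0})"
            )
    if voxel_size_um is None:
        logs = sorted(directory.glob("*.log"))
        for lp in logs:
            try:
                voxel_size_um = read_dataset_log(lp).voxel_size_um
                break
            except PatsError:
                continue
        if voxel_size_um is None:
            raise InputError(
                "missing voxel size: pass voxel_size_um or provide a dataset log"
            )
    return VolumeImage(
        np.stack(slices), voxel_size_um=float(voxel_size_um), source=str(directory)
    )


def read_dataset_log(path: str | Path) -> AcquisitionMeta:
    """Parse a sectioned ``key=value`` scanner dataset log.

    Only a small documented key set is interpreted (pixel size, voltage,
    current, rotation step, filter); everything else is ignored.
    """
    path = Path(path)
    kv: dict[str, str] = {}
    for line in path.read_text(errors="replace").splitlines():
        line = line.strip()
        if not line or line.startswith(("[", "#", ";")):
            continue
        if "=" in line:
            k, _, v = line.partition("=")
            kv[k.strip().lower()] = v.strip()

    def lookup(field: str) -> str | None:
        for key in _LOG_KEYS[field]:
            if key in kv:
                return kv[key]
        return None

    raw = lookup("voxel_size_um")
    if raw is None:
        raise InputError(f"missing voxel size: no pixel-size key in {path.name}")
    try:
        voxel = float(raw)
    except ValueError as exc:
        raise InputError(f"missing voxel size: unparsable value {raw!r}") from exc

    def num(field: str) -> float | None:
        v = lookup(field)
        if v is None:
            return None
        m = re.match(r"[-+0-9.eE]+", v)
        return float(m.group()) if m else None

    return AcquisitionMeta(
        voxel_size_um=voxel,
        kv=num("kv"),
        ua=num("ua"),
        rotation_step_deg=num("rotation_step_deg"),
        filter=lookup("filter"),
    )


def write_dataset_log(meta: AcquisitionMeta, path: str | Path) -> Path:
    """Write acquisition metadata in the sectioned key=value log format."""
    path = Path(path)
    lines = ["[System]", f"Image Pixel Size (um)={meta.voxel_size_um}"]
    if meta.kv is not None:
        lines.append(f"Source Voltage (kV)={meta.kv}")
    if meta.ua is not None:
        lines.append(f"Source Current (uA)={meta.ua}")
    if meta.rotation_step_deg is not None:
        lines.append(f"Rotation Step (deg)={meta.rotation_step_deg}")
    if meta.filter is not None:
        lines.append(f"Filter={meta.filter}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _write_slices(
    data: np.ndarray, directory: Path, prefix: str, ext: str
) -> list[Path]:
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(data.shape[0]):
        p = directory / f"{prefix}{z:04d}{ext}"
        if ext in (".tif", ".tiff"):
            tifffile.imwrite(p, data[z])
        else:
            iio.imwrite(p, data[z])
        paths.append(p)
    return paths


def write_volume_stack(
    volume: VolumeImage, directory: str | Path, prefix: str = "slice", ext: str = ".bmp"
) -> list[Path]:
    """Write a grayscale volume as a slice stack (one image per z)."""
    data = volume.data
    if data.dtype == np.uint16 and ext == ".bmp":
        ext = ".tif"  # BMP cannot carry 16-bit grayscale
    return _write_slices(data, Path(directory), prefix, ext)


def write_roi_stack(
    mask: BinaryMask, directory: str | Path, prefix: str = "roi", ext: str = ".bmp"
) -> list[Path]:
    """Write a binary mask as a monochrome (8-bit {0,255}) slice stack.

    Re-reading with :func:`read_roi_stack` reproduces the mask exactly.
    """
    data = np.where(mask.data, np.uint8(255), np.uint8(0))
    return _write_slices(data, Path(directory), prefix, ext)


def read_roi_stack(
    directory: str | Path, pattern: str = "*", voxel_size_um: float = 1.0
) -> BinaryMask:
    """Read a monochrome ROI stack back into a :class:`BinaryMask`."""
    vol = read_slice_stack(directory, pattern, voxel_size_um=voxel_size_um)
    return BinaryMask(vol.data > 127, voxel_size_um=voxel_size_um)


def write_mesh_stl(
    mesh: TriangleMesh, path: str | Path, binary: bool = True
) -> Path:
    """Write a triangle mesh as an STL file (binary by default).

    Facet normals follow the right-hand rule from the vertex order.
    """
    if mesh.n_faces == 0:
        raise InputError("empty mesh")
    path = Path(path)
    tri = mesh.triangles()  # (n, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"pats binary stl".ljust(80, b"\0"))
            fh.write(struct.pack("<I", len(tri)))
            rec = np.zeros(
                len(tri),
                dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
            )
            rec["n"] = normals
            rec["v"] = tri
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid pats\n")
            for n, t in zip(normals, tri):
                fh.write(f"  facet normal {n[0]:e} {n[1]:e} {n[2]:e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:e} {v[1]:e} {v[2]:e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid pats\n")
    return path


def read_mesh_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    Vertices are not de-duplicated; faces index three fresh vertices each.
    """
    path = Path(path)
    head = path.read_bytes()[:512]
    is_ascii = head.lstrip().startswith(b"solid") and b"facet" in path.read_bytes()[:4096]
    if is_ascii:
        verts = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if parts and parts[0] == "vertex":
                verts.append([float(x) for x in parts[1:4]])
        tri = np.asarray(verts, dtype=np.float64).reshape(-1, 3, 3)
    else:
        raw = path.read_bytes()
        (n,) = struct.unpack_from("<I", raw, 80)
        rec = np.frombuffer(
            raw,
            dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
            count=n,
            offset=84,
        )
        tri = rec["v"].astype(np.float64)
    nfaces = len(tri)
    vertices = tri.reshape(-1, 3)
    faces = np.arange(3 * nfaces).reshape(-1, 3)
    return TriangleMesh(vertices, faces)


def write_morphometry_csv(results: dict, path: str | Path) -> Path:
    """Write one CSV row per analysed ROI.

    ``results`` maps a ROI name to a :class:`~pats.morphometry.MorphometryResult`
    (or anything with its ``to_dict``).
    """
    rows = []
    for name, res in results.items():
        d = res.to_dict() if hasattr(res, "to_dict") else dict(res)
        rows.append({"roi": name, **d})
    df = pd.DataFrame(rows)
    path = Path(path)
    df.to_csv(path, index=False)
    return path
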