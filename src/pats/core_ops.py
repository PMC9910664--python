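"""Binary image operators for the segmentation task list.

The operators here are the named steps of the automated lung segmentation
sequence: global thresholding, voxelwise boolean algebra, despeckling by
connected components, binary morphology with round/square elements, and the
per-slice shrink-wrap that fits an ROI to a body's outer contour.

Conventions (fixed, see docs/methods.md):

* foreground connectivity is 26 in 3D and 8 in 2D; background uses the
  complementary 6/4 connectivity, the standard duality that avoids
  topological paradoxes in hole filling;
* morphology pads beyond the image border with background for dilation and
  foreground for erosion, so closing never trims objects at the border;
* a "round" element is the set of pixel centres within Euclidean distance
  ``radius`` of the origin.

Round-element erosion/dilation use the Euclidean distance transform, which
is exact for this element family and far faster than convolution with an
81-pixel-wide disc.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .containers import BinaryMask, StructuringElement, VolumeImage
from .errors import PatsError, SegmentationError

log = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "StructuringElement",
    "threshold_global",
    "bitwise_combine",
    "despeckle",
    "morphological_operation",
    "shrinkwrap_roi",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def threshold_global(
    volume: VolumeImage,
    lo: int,
    hi: int,
    roi: BinaryMask | None = None,
) -> BinaryMask:
    """Global threshold: true where ``lo <= intensity <= hi`` (both inclusive).

    If ``roi`` is given the result is restricted to it; voxels outside the
    ROI are always false.
    """
    if not (0 <= lo <= hi <= volume.intensity_max):
        raise PatsError(f"invalid range: {lo}..{hi} for {volume.bit_depth}-bit data")
    out = (volume.data >= lo) & (volume.data <= hi)
    if roi is not None:
        if roi.shape != volume.shape:
            raise PatsError("roi shape mismatch")
        out &= roi.data
    mask = BinaryMask(out, volume.voxel_size_um)
    log.debug("threshold %d..%d -> %d voxels", lo, hi, mask.count())
    return mask


def bitwise_combine(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxelwise boolean algebra: AND, OR, SUB (= a AND NOT b), XOR, NOT_A."""
    if a.shape != b.shape:
        raise PatsError(f"shape mismatch: {a.shape} vs {b.shape}")
    op = op.upper()
    if op == "AND":
        out = a.data & b.data
    elif op == "OR":
        out = a.data | b.data
    elif op == "SUB":
        out = a.data & ~b.data
    elif op == "XOR":
        out = a.data ^ b.data
    elif op == "NOT_A":
        out = ~a.data
    else:
        raise PatsError(f"unknown bitwise op {op!r}")
    return a.like(out)


def _label(data: np.ndarray, space: str, foreground: bool) -> tuple[np.ndarray, int]:
    if data.ndim == 3:
        struct = _STRUCT_26 if foreground else _STRUCT_6
    else:
        struct = _STRUCT_8 if foreground else _STRUCT_4
    assert space in ("2D", "3D")
    return ndimage.label(data, structure=struct)


def _largest_label(labels: np.ndarray, n: int) -> int:
    """Largest component; ties go to the lexicographically smallest first voxel."""
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = sizes.max()
    cands = np.flatnonzero(sizes == best) + 1
    if len(cands) == 1:
        return int(cands[0])
    # C-order ravel is (z, y, x)-lexicographic, so the first occurrence of
    # each candidate decides the tie.
    flat = labels.ravel()
    firsts = [np.flatnonzero(flat == lab)[0] for lab in cands]
    return int(cands[int(np.argmin(firsts))])


def despeckle(
    mask: BinaryMask,
    mode: str = "sweep_keep_largest",
    space: str = "3D",
    size_threshold: int | None = None,
) -> BinaryMask:
    """Connected-component despeckling.

    ``sweep_keep_largest``
        keep only the single largest foreground component (per slice in 2D);
    ``remove_white_smaller_than``
        drop foreground components with fewer than ``size_threshold`` voxels;
    ``remove_black_smaller_than``
        fill background components with fewer than ``size_threshold`` voxels
        (background uses complementary connectivity).
    """
    if mode not in (
        "sweep_keep_largest",
        "remove_white_smaller_than",
        "remove_black_smaller_than",
    ):
        raise PatsError(f"unknown despeckle mode {mode!r}")
    if space not in ("2D", "3D"):
        raise PatsError(f"unknown space {space!r}")

    def per_volume(data: np.ndarray) -> np.ndarray:
        if mode == "sweep_keep_largest":
            labels, n = _label(data, space, foreground=True)
            if n == 0:
                raise SegmentationError("no objects")
            return labels == _largest_label(labels, n)
        if size_threshold is None or size_threshold < 1:
            raise PatsError("size_threshold >= 1 required for size modes")
        if mode == "remove_white_smaller_than":
            labels, n = _label(data, space, foreground=True)
            if n == 0:
                return data.copy()
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < size_threshold)
            small = small[small > 0]
            return data & ~np.isin(labels, small)
        # remove_black: fill small background pores
        labels, n = _label(~data, space, foreground=False)
        if n == 0:
            return data.copy()
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < size_threshold)
        small = small[small > 0]
        return data | np.isin(labels, small)

    if space == "2D":
        out = np.zeros_like(mask.data)
        for z in range(mask.shape[0]):
            sl = mask.data[z]
            if mode == "sweep_keep_largest" and not sl.any():
                continue
            out[z] = per_volume(sl)
        if mode == "sweep_keep_largest" and not out.any():
            raise SegmentationError("no objects")
    else:
        out = per_volume(mask.data)
    result = mask.like(out)
    log.debug("despeckle %s/%s: %d -> %d voxels", mode, space, mask.count(), result.count())
    return result


def _round_dilate(data: np.ndarray, radius: int) -> np.ndarray:
    """Exact Euclidean-disc dilation; border treated as background."""
    if radius == 0 or not data.any():
        return data.copy()
    d = ndimage.distance_transform_edt(~data)
    return d <= radius


def _round_erode(data: np.ndarray, radius: int) -> np.ndarray:
    """Exact Euclidean-disc erosion; border treated as foreground."""
    if radius == 0:
        return data.copy()
    # distance to nearest background voxel must exceed the radius; no
    # padding needed because scipy's EDT only measures to zeros inside the
    # array, which is exactly the foreground-at-border contract.
    if data.all():
        return data.copy()
    d = ndimage.distance_transform_edt(data)
    return d > radius


def _apply_morph(data: np.ndarray, op: str, element: StructuringElement) -> np.ndarray:
    if element.shape == "round":
        dil = lambda m: _round_dilate(m, element.radius)  # noqa: E731
        ero = lambda m: _round_erode(m, element.radius)  # noqa: E731
    else:
        fp = element.footprint()
        dil = lambda m: ndimage.binary_dilation(m, structure=fp, border_value=0)  # noqa: E731
        ero = lambda m: ndimage.binary_erosion(m, structure=fp, border_value=1)  # noqa: E731
    if op == "dilation":
        return dil(data)
    if op == "erosion":
        return ero(data)
    if op == "closing":
        return ero(dil(data))
    if op == "opening":
        return dil(ero(data))
    raise PatsError(f"unknown morphological op {op!r}")


def morphological_operation(
    mask: BinaryMask,
    op: str,
    element: StructuringElement,
    roi: BinaryMask | None = None,
) -> BinaryMask:
    """Binary erosion/dilation/opening/closing with the given element.

    2D elements are applied independently per z-slice.  If ``roi`` is given
    the output is restricted to it.
    """
    if element.space == "2D":
        out = np.zeros_like(mask.data)
        for z in range(mask.shape[0]):
            out[z] = _apply_morph(mask.data[z], op, element)
    else:
        out = _apply_morph(mask.data, op, element)
    if roi is not None:
        if roi.shape != mask.shape:
            raise PatsError("roi shape mismatch")
        out &= roi.data
    result = mask.like(out)
    log.debug(
        "%s r=%d %s/%s: %d -> %d voxels",
        op, element.radius, element.shape, element.space, mask.count(), result.count(),
    )
    return result


def shrinkwrap_roi(
    body: BinaryMask,
    stretch_over_holes: bool = True,
    diameter: int = 4,
) -> BinaryMask:
    """Fit a per-slice ROI to the outer contour of the foreground.

    For each slice: (1) close the foreground with a round element of radius
    ``ceil(diameter/2)`` so surface openings of width <= ``diameter`` are
    bridged; (2) flood-fill the background from the slice border
    (4-connectivity); (3) the ROI is the complement of that exterior;
    (4) intersect with the dilation of the filled convex hull of the
    original foreground, a guard that the wrap never extends outward by
    more than the bridging radius.  Slices with empty foreground yield an
    empty ROI.
    """
    if not body.data.any():
        raise SegmentationError("nothing to wrap")
    radius = int(np.ceil(diameter / 2)) if stretch_over_holes else 0
    out = np.zeros_like(body.data)
    for z in range(body.shape[0]):
        fg = body.data[z]
        if not fg.any():
            continue
        closed = _round_erode(_round_dilate(fg, radius), radius) if radius else fg
        wrap = ndimage.binary_fill_holes(closed, structure=_STRUCT_4)
        hull = convex_hull_image(fg)
        out[z] = wrap & _round_dilate(hull, radius)
    return body.like(out)
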