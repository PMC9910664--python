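"""Task-list execution engine and the canonical segmentation sequences.

A *task list* is an ordered script of image-processing steps executed
against a mutable state of three layers: the immutable original grayscale
image, the current ROI, and the current binary selection.  The shipped
default list automates pulmonary air and tissue segmentation (PATS) for
thoracic microCT:

1.  threshold the body from surrounding air (55-255 on 8-bit data);
2.  shrink-wrap the body per slice (bridging openings up to 4 px);
3.  reload the image and threshold air (0-55) inside the body ROI;
4.  the ROI becomes "air within the body"; a 3D sweep despeckle keeps the
    single largest component: the aerated lung (lungs plus conducting
    airways are one connected air space);
5.  the aerated ROI is saved, analysed (basic values) and meshed;
6.  a per-slice round closing of radius 40 fills vessels, lesions and other
    holes, turning the aerated ROI into a whole-lung ROI;
7.  the image is reloaded and tissue (55-255) is thresholded inside the
    whole-lung ROI; a per-slice round erosion of radius 1 strips the rim of
    peripheral (chest-wall) tissue pulled in by the closing; the result is
    the vessels-and-dense-tissue ROI, saved, analysed (basic + additional
    values) and meshed.

Thresholds are expressed in native image units and are never rescaled for
16-bit input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io_volumes, morphometry
from .containers import BinaryMask, StructuringElement, TriangleMesh, VolumeImage
from .core_ops import (
    bitwise_combine,
    despeckle,
    morphological_operation,
    shrinkwrap_roi,
    threshold_global,
)
from .errors import PatsError, SegmentationError, TaskListError
from .morphometry import MorphometryResult, compute_morphometry, marching_cubes_mesh

log = logging.getLogger(__name__)

__all__ = [
    "PipelineState",
    "TaskStep",
    "TaskList",
    "PatsParams",
    "PatsResult",
    "reload_image",
    "run_task_list",
    "default_task_list",
    "load_task_list",
    "save_task_list",
    "pats_segment",
    "ex_vivo_segment",
]


@dataclass
class PipelineState:
    """The task-list machine state: original image, current ROI, selection."""

    image: VolumeImage
    roi: BinaryMask
    selection: BinaryMask | None = None
    annotations: list[str] = field(default_factory=list)

    @classmethod
    def initial(cls, volume: VolumeImage, roi: BinaryMask | None = None) -> "PipelineState":
        if roi is None:
            roi = BinaryMask(
                np.ones(volume.shape, dtype=bool), volume.voxel_size_um
            )
        if roi.shape != volume.shape:
            raise PatsError("roi shape mismatch")
        return cls(image=volume, roi=roi)


def reload_image(state: PipelineState) -> PipelineState:
    """Discard the binary selection; the grayscale image becomes the active
    layer again, with subsequent operations restricted to the current ROI."""
    return replace(state, selection=None)


@dataclass
class TaskStep:
    """One operation descriptor of a task list."""

    name: str
    params: dict = field(default_factory=dict)
    optional: bool = False
    enabled: bool = True


@dataclass
class TaskList:
    """An ordered, executable list of operation descriptors."""

    steps: list[TaskStep] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        for i, s in enumerate(self.steps):
            if s.name not in _OPERATIONS:
                raise TaskListError(f"unresolvable step {s.name!r} (step {i + 1})")

    def __len__(self) -> int:
        return len(self.steps)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaskList) and self.steps == other.steps


# ---------------------------------------------------------------------------
# step implementations: each takes (state, executor, **params) and returns
# the new state.


def _step_threshold(state, ex, lo: int, hi: int):
    sel = threshold_global(state.image, int(lo), int(hi), roi=state.roi)
    return replace(state, selection=sel)


def _step_shrinkwrap(state, ex, diameter: int = 4, stretch_over_holes: bool = True):
    if state.selection is None:
        raise PatsError("shrink-wrap needs a binary selection")
    roi = shrinkwrap_roi(
        state.selection, stretch_over_holes=bool(stretch_over_holes),
        diameter=int(diameter),
    )
    return replace(state, roi=roi)


def _step_reload(state, ex):
    return reload_image(state)


def _step_bitwise(state, ex, dst: str = "roi", a: str = "selection",
                  op: str = "AND", b: str = "roi"):
    layers = {"roi": state.roi, "selection": state.selection}

    def get(name):
        v = layers.get(name)
        if v is None:
            raise PatsError(f"bitwise operand {name!r} not set")
        return v

    out = bitwise_combine(get(a), get(b), op)
    if dst == "roi":
        return replace(state, roi=out)
    if dst == "selection":
        return replace(state, selection=out)
    raise PatsError(f"unknown bitwise destination {dst!r}")


def _step_despeckle(state, ex, mode: str = "sweep_keep_largest",
                    space: str = "3D", size_threshold=None,
                    target: str = "roi"):
    src = state.roi if target == "roi" else state.selection
    if src is None:
        raise PatsError("despeckle needs a binary layer")
    out = despeckle(src, mode=mode, space=space,
                    size_threshold=None if size_threshold is None else int(size_threshold))
    if target == "roi":
        return replace(state, roi=out)
    return replace(state, selection=out)


def _step_morphology(state, ex, op: str, shape: str = "round",
                     radius: int = 1, space: str = "2D", target: str = "roi"):
    elem = StructuringElement(shape=shape, radius=int(radius), space=space)
    if target == "roi":
        return replace(state, roi=morphological_operation(state.roi, op, elem))
    if state.selection is None:
        raise PatsError("morphology target is the selection but none is set")
    return replace(
        state, selection=morphological_operation(state.selection, op, elem)
    )


def _step_comment(state, ex, text: str = ""):
    state.annotations.append(text)
    return state


def _step_save_bitmaps(state, ex, name: str = "roi"):
    ex.artifacts[f"roi:{name}"] = state.roi.copy()
    if ex.out_dir is not None:
        io_volumes.write_roi_stack(state.roi, Path(ex.out_dir) / name, prefix=name)
    return state


def _step_analyze(state, ex, name: str = "analysis", values: str = "basic"):
    obj = (
        state.roi
        if state.selection is None
        else state.roi.like(state.roi.data & state.selection.data)
    )
    res = compute_morphometry(
        obj, voi=state.roi, additional=("additional" in values)
    )
    ex.artifacts[f"morphometry:{name}"] = res
    return state


def _step_model(state, ex, name: str = "model", format: str = "stl"):
    mesh = marching_cubes_mesh(state.roi)
    ex.artifacts[f"mesh:{name}"] = mesh
    if ex.out_dir is not None:
        io_volumes.write_mesh_stl(mesh, Path(ex.out_dir) / f"{name}.stl")
    return state


_OPERATIONS = {
    "threshold": _step_threshold,
    "shrinkwrap": _step_shrinkwrap,
    "reload": _step_reload,
    "bitwise": _step_bitwise,
    "despeckle": _step_despeckle,
    "morphology": _step_morphology,
    "comment": _step_comment,
    "save_bitmaps": _step_save_bitmaps,
    "analyze": _step_analyze,
    "model": _step_model,
}


class _Executor:
    def __init__(self, out_dir=None):
        self.out_dir = out_dir
        self.artifacts: dict = {}
        self.log: list[dict] = []


def run_task_list(
    volume: VolumeImage,
    tasks: TaskList,
    out_dir: str | Path | None = None,
    initial_roi: BinaryMask | None = None,
) -> tuple[PipelineState, dict, list[dict]]:
    """Execute the steps of ``tasks`` in order against a fresh state.

    Returns ``(final_state, artifacts, step_log)``.  Artifacts map
    ``"roi:<name>"``, ``"morphometry:<name>"`` and ``"mesh:<name>"`` keys to
    the saved objects; with ``out_dir`` set they are also written to disk.
    Disabled optional steps are skipped and logged.  A step whose
    precondition fails aborts with the step index.
    """
    state = PipelineState.initial(volume, roi=initial_roi)
    ex = _Executor(out_dir=out_dir)
    for i, step in enumerate(tasks.steps):
        entry = {"step": i + 1, "name": step.name, "params": dict(step.params)}
        if step.optional and not step.enabled:
            entry["skipped"] = True
            ex.log.append(entry)
            log.debug("step %d (%s): optional, disabled -> skipped", i + 1, step.name)
            continue
        fn = _OPERATIONS.get(step.name)
        if fn is None:
            raise TaskListError(f"unresolvable step {step.name!r} (step {i + 1})")
        try:
            state = fn(state, ex, **step.params)
        except PatsError as exc:
            raise type(exc)(f"step {i + 1} ({step.name}): {exc}") from exc
        entry["roi_voxels"] = state.roi.count()
        entry["selection_voxels"] = (
            None if state.selection is None else state.selection.count()
        )
        ex.log.append(entry)
    return state, ex.artifacts, ex.log


# ---------------------------------------------------------------------------
# canonical parameterisation and sequences


@dataclass
class PatsParams:
    """Tunable parameters of the automated air/tissue segmentation.

    Defaults are the published task-list values for 8-bit reconstructions:
    body/tissue threshold 55-255, air threshold 0-55 (both inclusive; the
    two ranges deliberately share intensity 55), shrink-wrap bridging
    diameter 4 px, per-slice round closing radius 40 px, per-slice round
    erosion radius 1 px.
    """

    body_threshold: tuple[int, int] = (55, 255)
    air_threshold: tuple[int, int] = (0, 55)
    shrinkwrap_diameter: int = 4
    closing_radius: int = 40
    erosion_radius: int = 1
    enable_optional_despeckle: bool = False
    enable_manual_roi_export: bool = False
    manual_pre_roi: BinaryMask | None = None

    def validate(self, bit_depth: int = 8) -> None:
        imax = (1 << bit_depth) - 1
        for lo, hi in (self.body_threshold, self.air_threshold):
            if not (0 <= lo <= hi <= imax):
                raise PatsError(f"invalid range: {lo}..{hi}")
        if min(self.shrinkwrap_diameter, self.closing_radius, self.erosion_radius) < 0:
            raise PatsError("radii must be >= 0")


@dataclass
class PatsResult:
    """Output bundle of the automated segmentation."""

    aerated_roi: BinaryMask
    tissue_roi: BinaryMask
    aerated_morphometry: MorphometryResult
    tissue_morphometry: MorphometryResult
    aerated_mesh: TriangleMesh | None
    tissue_mesh: TriangleMesh | None
    log: list[dict] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)


def default_task_list(
    params: PatsParams | None = None,
    include_tissue_outputs: bool = True,
) -> TaskList:
    """The canonical automated air/tissue task list (20 operational steps).

    ``include_tissue_outputs=False`` truncates after the final bitwise step
    so a caller can post-process the tissue ROI before analysing it.
    """
    p = params or PatsParams()
    blo, bhi = p.body_threshold
    alo, ahi = p.air_threshold
    steps = [
        TaskStep("threshold", {"lo": blo, "hi": bhi}),
        TaskStep("shrinkwrap", {"diameter": p.shrinkwrap_diameter,
                                "stretch_over_holes": True}),
        TaskStep("reload"),
        TaskStep("threshold", {"lo": alo, "hi": ahi}),
        TaskStep("bitwise", {"dst": "roi", "a": "selection", "op": "AND", "b": "roi"}),
        TaskStep("despeckle", {"mode": "sweep_keep_largest", "space": "3D",
                               "target": "roi"}),
        TaskStep("despeckle", {"mode": "sweep_keep_largest", "space": "3D",
                               "target": "roi"},
                 optional=True, enabled=p.enable_optional_despeckle),
        TaskStep("save_bitmaps", {"name": "aerated_lung"}),
        TaskStep("analyze", {"name": "aerated_lung", "values": "basic"}),
        TaskStep("model", {"name": "aerated_lung", "format": "stl"}),
        TaskStep("morphology", {"op": "closing", "shape": "round",
                                "radius": p.closing_radius, "space": "2D",
                                "target": "roi"}),
        TaskStep("bitwise", {"dst": "roi", "a": "selection", "op": "AND", "b": "roi"},
                 optional=True, enabled=False),
        TaskStep("save_bitmaps", {"name": "roi_for_modification"},
                 optional=True, enabled=p.enable_manual_roi_export),
        TaskStep("reload"),
        TaskStep("threshold", {"lo": blo, "hi": bhi}),
        TaskStep("morphology", {"op": "erosion", "shape": "round",
                                "radius": p.erosion_radius, "space": "2D",
                                "target": "selection"}),
        TaskStep("bitwise", {"dst": "roi", "a": "roi", "op": "AND", "b": "selection"}),
    ]
    if include_tissue_outputs:
        steps += [
            TaskStep("save_bitmaps", {"name": "lung_tissue"}),
            TaskStep("analyze", {"name": "lung_tissue",
                                 "values": "basic,additional"}),
            TaskStep("model", {"name": "lung_tissue", "format": "stl"}),
        ]
    return TaskList(steps=steps, provenance="built-in PATS defaults")


def pats_segment(
    volume: VolumeImage,
    params: PatsParams | None = None,
    out_dir: str | Path | None = None,
    make_meshes: bool = True,
) -> PatsResult:
    """Automated pulmonary air and tissue segmentation.

    Runs the default task list: the aerated ROI is the largest connected
    air component inside the shrink-wrapped body; the tissue ROI contains
    the tissue-range voxels inside the closed aerated ROI after one
    per-slice round erosion.  The two ROIs are made disjoint (voxels of
    intensity near the shared threshold can fall in both ranges); the
    overlap count is logged.
    """
    params = params or PatsParams()
    params.validate(volume.bit_depth)
    tasks = default_task_list(params, include_tissue_outputs=False)
    if not make_meshes:
        tasks = TaskList(
            [s for s in tasks.steps if s.name != "model"], tasks.provenance
        )
    try:
        state, artifacts, step_log = run_task_list(
            volume, tasks, out_dir=out_dir, initial_roi=params.manual_pre_roi
        )
    except SegmentationError as exc:
        if "no objects" in str(exc):
            raise SegmentationError("segmentation failed: no lung air") from exc
        raise

    aerated = artifacts["roi:aerated_lung"]
    if aerated.volume_mm3() < 1.0:
        log.warning(
            "implausible lung volume: aerated ROI is %.4f mm^3",
            aerated.volume_mm3(),
        )
    log.warning(
        "per-slice erosion of the tissue selection may remove some tissue "
        "within the lung"
    )

    tissue = state.roi
    overlap = int((tissue.data & aerated.data).sum())
    if overlap:
        log.info(
            "%d voxels fell in both the air and tissue ranges (shared "
            "threshold); removed from the tissue ROI", overlap,
        )
        tissue = tissue.like(tissue.data & ~aerated.data)
    step_log.append({"step": "disjoint", "overlap_voxels": overlap,
                     "tissue_voxels": tissue.count()})

    tissue_morph = compute_morphometry(tissue, voi=tissue, additional=True)
    aerated_mesh = artifacts.get("mesh:aerated_lung")
    tissue_mesh = None
    if make_meshes and tissue.data.any():
        tissue_mesh = marching_cubes_mesh(tissue)
    if out_dir is not None:
        io_volumes.write_roi_stack(
            tissue, Path(out_dir) / "lung_tissue", prefix="lung_tissue"
        )
        if tissue_mesh is not None:
            io_volumes.write_mesh_stl(
                tissue_mesh, Path(out_dir) / "lung_tissue.stl"
            )
    return PatsResult(
        aerated_roi=aerated,
        tissue_roi=tissue,
        aerated_morphometry=artifacts["morphometry:aerated_lung"],
        tissue_morphometry=tissue_morph,
        aerated_mesh=aerated_mesh,
        tissue_mesh=tissue_mesh,
        log=step_log,
        annotations=list(state.annotations),
    )


def ex_vivo_segment(
    volume: VolumeImage,
    tissue_threshold: tuple[int, int] = (55, 255),
    out_dir: str | Path | None = None,
    make_mesh: bool = True,
) -> tuple[MorphometryResult, BinaryMask, TriangleMesh | None]:
    """Quantify a dried/fixed ex vivo lung scan (air background, tissue
    foreground): threshold, keep the largest connected component, then
    compute tissue volume, structure thickness and structure linear density.
    """
    lo, hi = tissue_threshold
    sel = threshold_global(volume, lo, hi)
    if not sel.data.any():
        raise SegmentationError("segmentation failed: empty tissue mask")
    tissue = despeckle(sel, mode="sweep_keep_largest", space="3D")
    res = compute_morphometry(tissue, voi=tissue, additional=True)
    mesh = marching_cubes_mesh(tissue) if make_mesh else None
    if out_dir is not None:
        io_volumes.write_roi_stack(tissue, Path(out_dir) / "tissue", prefix="tissue")
        if mesh is not None:
            io_volumes.write_mesh_stl(mesh, Path(out_dir) / "tissue.stl")
    return res, tissue, mesh


# ---------------------------------------------------------------------------
# task-list files: one step per line, "name key=value key=value ..."


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    return str(v)


def _parse_value(s: str):
    if s.lower() in ("true", "false"):
        return s.lower() == "true"
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def save_task_list(tasks: TaskList, path: str | Path) -> Path:
    """Write a task list in the line-oriented text format (round-trip stable)."""
    path = Path(path)
    lines = ["# pats task list"]
    if tasks.provenance:
        lines.append(f"# provenance: {tasks.provenance}")
    for s in tasks.steps:
        toks = [s.name]
        toks += [f"{k}={_fmt_value(v)}" for k, v in s.params.items()]
        if s.optional:
            toks.append("optional=true")
            toks.append(f"enabled={_fmt_value(s.enabled)}")
        lines.append(" ".join(toks))
    path.write_text("\n".join(lines) + "\n")
    return path


def shipped_task_list_path() -> Path:
    """Path of the default task-list file distributed with the package."""
    return Path(__file__).parent / "data" / "pats_default.tasklist"


def load_task_list(path: str | Path) -> TaskList:
    """Parse a task-list file; schema violations name the offending line."""
    path = Path(path)
    steps: list[TaskStep] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        name = toks[0]
        if name not in _OPERATIONS:
            raise TaskListError(
                f"line {lineno}: unresolvable step {name!r}"
            )
        params: dict = {}
        optional = False
        enabled = True
        for tok in toks[1:]:
            if "=" not in tok:
                raise TaskListError(
                    f"line {lineno}: expected key=value, got {tok!r}"
                )
            k, _, v = tok.partition("=")
            val = _parse_value(v)
            if k == "optional":
                optional = bool(val)
            elif k == "enabled":
                enabled = bool(val)
            else:
                params[k] = val
        steps.append(TaskStep(name, params, optional=optional, enabled=enabled))
    return TaskList(steps=steps, provenance=str(path))
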