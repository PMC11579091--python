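"""End-to-end orchestration: detect -> link -> match -> landmarks ->
register -> transfer -> report.

Each brain is processed independently and failures are isolated: one
degenerate crop marks that brain ``registration_failed`` and the rest of the
slide still completes. Registration operates on inverted luminance (tissue
bright on zero background) so the zero fill of backward warping blends with
the background instead of fighting the similarity metric. All outputs are a
pure function of (inputs, config, seed); reports serialize with sorted keys
so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .atlas_match import MatchConfig, match_layer
from .core import Image
from .detect import DetectionConfig, centroid_grid, crop_brain, detect_objects
from .evaluate import f1_mask, transfer_roi
from .landmarks import (
    CorrespondenceConfig,
    LandmarkPairs,
    detect_correspondences,
    filter_pairs,
    read_landmarks,
)
from .link import assign, grid_from_metadata, label_brains, standardize
from .register import (
    DisplacementField,
    RegistrationConfig,
    SimilarityTransform,
    affine_register,
    elastic_register,
)
from .slide_io import (
    MetadataTable,
    RoiAnnotation,
    TemplateStack,
    read_image,
    read_metadata,
    read_stack,
    roi_from_mask,
    write_annotations,
)

__all__ = ["PipelineConfig", "BrainResult", "run_slide", "run_pair", "evaluate_against_phantom"]

log = logging.getLogger("brainslide")


@dataclass
class PipelineConfig:
    """All knobs of a slide run; ``seed`` fixed means fully reproducible."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    match: MatchConfig = field(default_factory=lambda: MatchConfig(invert=True))
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    correspondence: CorrespondenceConfig = field(default_factory=CorrespondenceConfig)
    landmark_source: str = "auto"  # {"auto", "file", "none"}
    landmark_files: dict[str, str] | None = None  # sample label -> CSV path
    crop_pad: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_source not in {"auto", "file", "none"}:
            raise ValueError(f"unknown landmark source {self.landmark_source!r}")

    def hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return repr(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BrainResult:
    """Everything the pipeline produced for one brain."""

    sample: str
    group: str
    cell: tuple[int, int] | None
    object_index: int
    status: str = "ok"  # {"ok", "unmatched", "registration_failed"}
    message: str = ""
    matched_layer: int = -1
    layer_scores: dict[int, float] = field(default_factory=dict)
    affine: SimilarityTransform | None = None
    affine_loss: float = float("nan")
    elastic: DisplacementField | None = None
    trace: list = field(default_factory=list)  # LossBreakdown per iteration
    n_landmarks: int = 0
    rois: list[RoiAnnotation] = field(default_factory=list)  # crop frame
    crop_origin: tuple[int, int] = (0, 0)
    crop_shape: tuple[int, int] = (0, 0)
    f1: dict[str, float] = field(default_factory=dict)


def _norm_grid(ps):
    """Standardize when possible; degenerate grids (a single point, or zero
    variance on both axes) are centered only so assignment still works."""
    from .core import PointSet

    if ps.n >= 2 and np.any(ps.xy.std(axis=0) > 1e-12):
        return standardize(ps)
    return PointSet(ps.xy - ps.xy.mean(axis=0))


def _register_one(
    crop: Image,
    stack: TemplateStack,
    cfg: PipelineConfig,
    pairs: LandmarkPairs | None,
    result: BrainResult,
) -> None:
    """Match + landmarks + two-stage registration + ROI transfer, in place."""
    fixed = 1.0 - crop.pixels  # tissue bright, background ~0
    t0 = time.perf_counter()
    match = match_layer(crop, stack, cfg.match)
    result.matched_layer = match.layer_id
    result.layer_scores = match.scores
    log.info("matched layer %d in %.1fs", match.layer_id, time.perf_counter() - t0)

    layer_img, layer_masks = stack.layer(match.layer_id)
    moving = 1.0 - layer_img.pixels

    if pairs is None and cfg.landmark_source == "auto":
        pairs = filter_pairs(detect_correspondences(moving, fixed, cfg.correspondence),
                             cfg.correspondence)
    if pairs is not None and len(pairs) == 0:
        pairs = None
    result.n_landmarks = 0 if pairs is None else len(pairs)

    t0 = time.perf_counter()
    aff = affine_register(fixed, moving, cfg.registration)
    result.affine = aff.transform
    result.affine_loss = aff.final_loss
    log.info("affine stage %.1fs (loss %.4g)", time.perf_counter() - t0, aff.final_loss)

    t0 = time.perf_counter()
    ela = elastic_register(fixed, moving, init=aff.transform, pairs=pairs, cfg=cfg.registration)
    result.elastic = ela.field
    result.trace = ela.trace
    log.info("elastic stage %.1fs (loss %.4g)", time.perf_counter() - t0, ela.trace[-1].total)

    for name, mask in sorted(layer_masks.items()):
        roi = roi_from_mask(name, mask, source_layer=match.layer_id)
        result.rois.append(
            transfer_roi(roi, aff.transform, ela.field, target_shape=fixed.shape)
        )


def run_slide(
    slide,
    metadata,
    stack,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[BrainResult], dict]:
    """Run the full pipeline on a multi-brain slide.

    ``slide``, ``metadata`` and ``stack`` may be paths or in-memory objects.
    Returns the per-brain results and a machine-readable report; when
    ``out_dir`` is given the report, per-brain GeoJSON annotations and
    transform containers are written there.
    """
    cfg = cfg or PipelineConfig()
    slide_img = read_image(slide) if isinstance(slide, (str, Path)) else slide
    if not isinstance(slide_img, Image):
        slide_img = Image(np.asarray(slide_img))
    table = read_metadata(metadata) if isinstance(metadata, (str, Path)) else metadata
    tstack = read_stack(stack) if isinstance(stack, (str, Path)) else stack

    objects = detect_objects(slide_img, cfg.detection)
    grid = centroid_grid(objects)
    cell_pts, cell_keys = grid_from_metadata(table)

    results: list[BrainResult] = []
    missing: list[tuple[int, int]] = sorted(table.cells.keys())
    if grid.points.n >= 1:
        assignment = assign(_norm_grid(grid.points), _norm_grid(cell_pts))
        labeled, missing = label_brains(
            assignment, table, objects, cell_keys, brain_indices=grid.provenance
        )
    else:
        labeled = []

    for rec in labeled:
        obj = objects[rec["object_index"]]
        res = BrainResult(
            sample=rec["sample"],
            group=rec["group"],
            cell=tuple(rec["cell"]),
            object_index=rec["object_index"],
        )
        results.append(res)
        try:
            crop, origin = crop_brain(slide_img, obj, pad=cfg.crop_pad)
            res.crop_origin = origin
            res.crop_shape = crop.shape
            pairs = None
            if cfg.landmark_source == "file":
                files = cfg.landmark_files or {}
                if rec["sample"] not in files:
                    raise FileNotFoundError(f"no landmark file for sample {rec['sample']!r}")
                pairs = read_landmarks(files[rec["sample"]])
            elif cfg.landmark_source == "none":
                pairs = None
            _register_one(crop, tstack, cfg, pairs, res)
        except Exception as exc:  # noqa: BLE001 - per-brain isolation
            res.status = "registration_failed"
            res.message = f"{type(exc).__name__}: {exc}"
            log.warning("brain %s failed: %s", res.sample, res.message)

    report = _build_report(cfg, slide_img, objects, results, missing)
    if out_dir is not None:
        _write_outputs(Path(out_dir), cfg, results, report)
    return results, report


def run_pair(
    fixed,
    moving,
    landmarks=None,
    cfg: PipelineConfig | None = None,
    rois: list[RoiAnnotation] | None = None,
) -> BrainResult:
    """Registration-only entry point for a single (fixed, moving) pair.

    Images are used as given (no luminance inversion); ``landmarks`` may be
    a CSV path or a :class:`LandmarkPairs`. Optional ``rois`` defined on the
    moving image are transferred through the composed transform.
    """
    cfg = cfg or PipelineConfig()
    fixed_img = read_image(fixed) if isinstance(fixed, (str, Path)) else fixed
    moving_img = read_image(moving) if isinstance(moving, (str, Path)) else moving
    fixed_px = fixed_img.pixels if isinstance(fixed_img, Image) else np.asarray(fixed_img, float)
    moving_px = (
        moving_img.pixels if isinstance(moving_img, Image) else np.asarray(moving_img, float)
    )

    pairs = None
    if isinstance(landmarks, (str, Path)):
        pairs = read_landmarks(landmarks)
    elif landmarks is not None:
        pairs = landmarks
    elif cfg.landmark_source == "auto":
        pairs = filter_pairs(
            detect_correspondences(moving_px, fixed_px, cfg.correspondence), cfg.correspondence
        )
    if cfg.landmark_source == "file" and pairs is None:
        raise FileNotFoundError("landmark source is 'file' but no landmark file was given")
    if pairs is not None and len(pairs) == 0:
        pairs = None

    res = BrainResult(sample="pair", group="", cell=None, object_index=0)
    res.crop_shape = fixed_px.shape
    aff = affine_register(fixed_px, moving_px, cfg.registration)
    res.affine = aff.transform
    res.affine_loss = aff.final_loss
    ela = elastic_register(fixed_px, moving_px, init=aff.transform, pairs=pairs, cfg=cfg.registration)
    res.elastic = ela.field
    res.trace = ela.trace
    res.n_landmarks = 0 if pairs is None else len(pairs)
    for roi in rois or []:
        res.rois.append(transfer_roi(roi, aff.transform, ela.field, fixed_px.shape))
    return res


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _affine_dict(t: SimilarityTransform | None) -> dict | None:
    if t is None:
        return None
    return {
        "rotation": t.rotation,
        "scale": t.scale,
        "reflection": bool(t.reflection),
        "translation": list(t.translation),
        "center": list(t.center),
    }


def _build_report(cfg, slide_img, objects, results, missing) -> dict:
    return {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "slide_shape": list(slide_img.shape),
        "n_objects": {
            "brain": sum(1 for o in objects if o.klass == "brain"),
            "note": sum(1 for o in objects if o.klass == "note"),
        },
        "missing_cells": [list(c) for c in missing],
        "brains": [
            {
                "sample": r.sample,
                "group": r.group,
                "cell": list(r.cell) if r.cell is not None else None,
                "status": r.status,
                "message": r.message,
                "matched_layer": r.matched_layer,
                "layer_scores": {str(k): v for k, v in sorted(r.layer_scores.items())},
                "affine": _affine_dict(r.affine),
                "affine_loss": r.affine_loss,
                "n_landmarks": r.n_landmarks,
                "crop_origin": list(r.crop_origin),
                "crop_shape": list(r.crop_shape),
                "rois": [a.name for a in r.rois],
                "f1": dict(r.f1),
                "loss_trace": [
                    [lb.ncc_term, lb.df_term, lb.lrt_term, lb.total] for lb in r.trace
                ],
            }
            for r in results
        ],
    }


def _write_outputs(out_dir: Path, cfg, results, report) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    for r in results:
        if r.status != "ok":
            continue
        stem = f"brain_{r.sample}"
        write_annotations(r.rois, out_dir / f"{stem}.geojson", format="geojson")
        np.savez(
            out_dir / f"{stem}_transform.npz",
            control_points=r.elastic.control_points,
            spacing=r.elastic.spacing,
            shape=np.array(r.elastic.shape),
            diffeomorphic=np.array(r.elastic.diffeomorphic),
            affine=np.array(
                [
                    r.affine.rotation,
                    r.affine.scale,
                    float(r.affine.reflection),
                    *r.affine.translation,
                    *r.affine.center,
                ]
            ),
        )


def evaluate_against_phantom(results: list[BrainResult], phantom_slide) -> dict[str, float]:
    """Dice of every transferred ROI against the phantom's truth masks.

    Truth ROI masks live in slide coordinates; each result's ROIs live in
    its crop frame, so the truth is cropped with the recorded origin before
    comparison. Returns mean Dice per ROI name plus ``"mean"`` overall, and
    stores per-brain scores in each result's ``f1`` mapping.
    """
    by_cell = {b.cell: b for b in phantom_slide.brains}
    per_name: dict[str, list[float]] = {}
    for r in results:
        if r.status != "ok" or r.cell not in by_cell:
            continue
        truth_brain = by_cell[r.cell]
        x0, y0 = r.crop_origin
        h, w = r.crop_shape
        for roi in r.rois:
            truth_roi = next((t for t in truth_brain.rois if t.name == roi.name), None)
            if truth_roi is None:
                continue
            truth_crop = truth_roi.mask[y0 : y0 + h, x0 : x0 + w]
            if not truth_crop.any():
                continue
            d = f1_mask(roi.mask, truth_crop)
            r.f1[roi.name] = d
            per_name.setdefault(roi.name, []).append(d)
    out = {name: float(np.mean(v)) for name, v in sorted(per_name.items())}
    allv = [d for v in per_name.values() for d in v]
    out["mean"] = float(np.mean(allv)) if allv else float("nan")
    return out
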