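"""Find brain-tissue objects and handwritten-note artifacts on a slide.

The baseline detector is classical: global intensity thresholding (Otsu on
the inverted slide, tissue being darker than the glass background),
morphological closing, connected components, and shape rules that separate
compact tissue blobs (high solidity) from thin ink strokes (low solidity or
small stroke width). It sits behind a plain functional interface — any
callable returning the same list of :class:`DetectedObject` (for example a
trained instance-segmentation model) can replace it without touching the
rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .core import Image, PointSet, as_pixels

__all__ = [
    "DetectedObject",
    "CentroidGrid",
    "DetectionConfig",
    "detect_objects",
    "centroid_grid",
    "crop_brain",
]


@dataclass
class DetectedObject:
    """One detected slide object (brain section or handwritten note).

    ``bbox`` is half-open ``(x_min, y_min, x_max, y_max)`` in pixels; ``mask``
    is the binary foreground within the bbox; ``centroid`` the (x, y) center
    of mass of the mask in slide coordinates.
    """

    klass: str  # {"brain", "note"}
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    centroid: tuple[float, float]
    score: float = 1.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        self.mask = np.asarray(self.mask).astype(bool)
        if not self.mask.any():
            raise ValueError("empty object mask")
        cx, cy = self.centroid
        if not (x0 <= cx <= x1 and y0 <= cy <= y1):
            raise ValueError("centroid outside bbox")


@dataclass
class CentroidGrid:
    """Centroids of the brain-class detections, in stable detection order."""

    points: PointSet
    provenance: list[int] = field(default_factory=list)  # indices into the object list


@dataclass
class DetectionConfig:
    """Thresholds of the classical detector (all in pixels / pixel counts)."""

    min_brain_area: int = 1500
    min_solidity: float = 0.80
    min_note_area: int = 30
    max_stroke_width: float = 4.0
    closing_radius: int = 2
    threshold: float | None = None  # None -> Otsu on the inverted slide


def _mean_stroke_width(mask: np.ndarray) -> float:
    """2x the mean distance-to-background over foreground pixels."""
    edt = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    return float(2.0 * edt[mask].mean())


def detect_objects(slide: Image | np.ndarray, cfg: DetectionConfig | None = None) -> list[DetectedObject]:
    """Detect brain and note objects; deterministic order by (y_min, x_min)."""
    px = as_pixels(slide)
    if px.shape[0] < 64 or px.shape[1] < 64:
        raise ValueError("slide must be at least 64x64")
    cfg = cfg or DetectionConfig()
    inv = 1.0 - px
    thr = cfg.threshold
    if thr is None:
        thr = float(threshold_otsu(inv))
    raw_fg = inv > thr
    fg = morphology.closing(raw_fg, morphology.disk(cfg.closing_radius))
    labels = measure.label(fg, connectivity=2)

    objects: list[DetectedObject] = []
    for region in measure.regionprops(labels):
        area = region.area
        if area < min(cfg.min_note_area, cfg.min_brain_area):
            continue
        solidity = region.solidity
        y0, x0, y1, x1 = region.bbox
        mask = region.image
        # stroke width on the pre-closing foreground: closing fattens thin
        # ink strokes and would disguise them as compact blobs
        raw = mask & raw_fg[y0:y1, x0:x1]
        if area >= cfg.min_brain_area and solidity >= cfg.min_solidity:
            klass = "brain"
        elif area >= cfg.min_note_area and (
            solidity < cfg.min_solidity
            or (raw.any() and _mean_stroke_width(raw) <= cfg.max_stroke_width)
        ):
            klass = "note"
        else:
            continue
        ys, xs = np.nonzero(mask)
        centroid = (x0 + float(xs.mean()), y0 + float(ys.mean()))
        objects.append(
            DetectedObject(
                klass=klass,
                bbox=(x0, y0, x1, y1),
                mask=mask,
                centroid=centroid,
                score=float(solidity) if klass == "brain" else float(1.0 - solidity),
            )
        )
    objects.sort(key=lambda o: (o.bbox[1], o.bbox[0]))
    return objects


def centroid_grid(objects: list[DetectedObject]) -> CentroidGrid:
    """Brain centroids only; an empty grid when nothing was detected."""
    idx = [i for i, o in enumerate(objects) if o.klass == "brain"]
    pts = np.array([objects[i].centroid for i in idx], dtype=float).reshape(-1, 2)
    return CentroidGrid(points=PointSet(pts), provenance=idx)


def crop_brain(slide: Image | np.ndarray, obj: DetectedObject, pad: int = 0) -> tuple[Image, tuple[int, int]]:
    """Crop a brain's bbox expanded by ``pad``, clipped to the slide.

    Returns the crop and its (x0, y0) origin in slide coordinates.
    """
    if obj.klass != "brain":
        raise ValueError(f"can only crop brain-class objects, got {obj.klass!r}")
    px = as_pixels(slide)
    x0, y0, x1, y1 = obj.bbox
    x0 = max(0, x0 - pad)
    y0 = max(0, y0 - pad)
    x1 = min(px.shape[1], x1 + pad)
    y1 = min(px.shape[0], y1 + pad)
    return Image(px[y0:y1, x0:x1]), (x0, y0)
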