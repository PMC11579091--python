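"""Readers and writers for slides, metadata layouts, template stacks,
landmark files, and annotation outputs.

Images are PNG or TIFF; on load they are scaled to [0, 1] and RGB is
collapsed to luminance (0.299 R + 0.587 G + 0.114 B). Metadata layouts come
from CSV or XLSX sheets whose cells hold sample labels (optionally
``sample/group``); blank cells mark positions without a sample. Vector ROI
output is GeoJSON in pixel coordinates (importable into QuPath and similar
viewers); raster output is an integer-coded label mask PNG with a sidecar
CSV mapping code to ROI name.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image as PILImage
from shapely.ops import unary_union
from skimage.draw import polygon as draw_polygon

from .core import Image

__all__ = [
    "MetadataTable",
    "TemplateStack",
    "RoiAnnotation",
    "read_image",
    "write_image",
    "read_metadata",
    "write_metadata",
    "read_stack",
    "write_stack",
    "roi_from_mask",
    "mask_from_polygon",
    "write_annotations",
    "read_annotations",
]

_LUMA = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> Image:
    """Load a PNG or TIFF as a grayscale [0, 1] image."""
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            with PILImage.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise IOError(f"cannot read image {path}: empty file")
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA  # drop alpha, collapse to luminance
    return Image(np.clip(arr, 0.0, 1.0))


def write_image(image: Image | np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] image as 8-bit PNG or 16-bit TIFF by extension."""
    px = image.pixels if isinstance(image, Image) else np.asarray(image, float)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, (np.clip(px, 0, 1) * 65535).astype(np.uint16))
    else:
        PILImage.fromarray((np.clip(px, 0, 1) * 255).round().astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# metadata layout tables
# ---------------------------------------------------------------------------


@dataclass
class MetadataTable:
    """Row/column layout of sample labels on a slide.

    ``cells`` maps 0-based ``(row, col)`` to ``(sample_label, group_label)``;
    positions absent from the mapping are explicitly empty. Sample labels are
    unique.
    """

    cells: dict[tuple[int, int], tuple[str, str]]
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        labels = [s for s, _ in self.cells.values()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate sample labels: {dupes}")
        for r, c in self.cells:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"cell ({r}, {c}) outside {self.n_rows}x{self.n_cols} grid")

    @property
    def n_filled(self) -> int:
        return len(self.cells)


def _parse_cell(text: str) -> tuple[str, str]:
    if "/" in text:
        sample, group = text.split("/", 1)
        return sample.strip(), group.strip()
    return text.strip(), ""


def read_metadata(path: str | Path) -> MetadataTable:
    """Read a layout table from CSV or XLSX (first sheet).

    Each non-blank spreadsheet cell holds a sample label, optionally
    ``sample/group``. Duplicate sample labels and fully empty tables are
    rejected.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".xlsx", ".xls"}:
            df = pd.read_excel(path, header=None, dtype=object)
        else:
            df = pd.read_csv(path, header=None, dtype=object, skip_blank_lines=False)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read metadata table {path}: {exc}") from exc
    cells: dict[tuple[int, int], tuple[str, str]] = {}
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            val = df.iat[r, c]
            if pd.isna(val) or str(val).strip() == "":
                continue
            cells[(r, c)] = _parse_cell(str(val))
    if not cells:
        raise ValueError(f"metadata table {path} is empty")
    return MetadataTable(cells, n_rows=df.shape[0], n_cols=df.shape[1])


def write_metadata(table: MetadataTable, path: str | Path) -> None:
    path = Path(path)
    grid = [["" for _ in range(table.n_cols)] for _ in range(table.n_rows)]
    for (r, c), (sample, group) in table.cells.items():
        grid[r][c] = f"{sample}/{group}" if group else sample
    df = pd.DataFrame(grid)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df.to_excel(path, header=False, index=False)
    else:
        df.to_csv(path, header=False, index=False)


# ---------------------------------------------------------------------------
# ROI annotations
# ---------------------------------------------------------------------------


@dataclass
class RoiAnnotation:
    """A named region as both binary mask and closed polygon ring(s)."""

    name: str
    mask: np.ndarray  # binary raster, full image frame
    polygons: list[np.ndarray] = field(default_factory=list)  # (K, 2) closed (x, y) rings
    source_layer: int = -1
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def roi_from_mask(name: str, mask: np.ndarray, source_layer: int = -1) -> RoiAnnotation:
    """Build an annotation from a binary mask.

    Polygons trace the exact pixel boundary (pixel (i, j) occupies the unit
    square centered on it), built as the union of per-row run rectangles
    with collinear vertices merged — a square mask yields a closed 5-point
    ring, and rasterizing the rings reproduces the mask exactly. Interior
    holes are not represented.
    """
    mask = np.asarray(mask).astype(bool)
    rects = []
    for y in range(mask.shape[0]):
        xs = np.flatnonzero(mask[y])
        if xs.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(xs) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [xs.size - 1]])
        for s, e in zip(starts, ends):
            rects.append(shapely.box(xs[s] - 0.5, y - 0.5, xs[e] + 0.5, y + 0.5))
    polys: list[np.ndarray] = []
    if rects:
        geom = unary_union(rects).simplify(0)
        parts = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for part in parts:
            ring = np.asarray(part.exterior.coords, dtype=float)
            polys.append(ring)
    return RoiAnnotation(name=name, mask=mask, polygons=polys, source_layer=source_layer)


def mask_from_polygon(polygons: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize closed (x, y) rings into a binary mask."""
    mask = np.zeros(shape, dtype=bool)
    for ring in polygons:
        ring = np.asarray(ring, float)
        rr, cc = draw_polygon(ring[:, 1], ring[:, 0], shape=shape)
        mask[rr, cc] = True
    return mask


def write_annotations(
    annots: list[RoiAnnotation], path: str | Path, format: str = "geojson"
) -> None:
    """Write ROI annotations as GeoJSON or an integer-coded label-mask PNG.

    In label-mask mode overlapping ROIs are rejected (their codes would
    collide); a sidecar ``<stem>_labels.csv`` maps code to ROI name.
    """
    path = Path(path)
    if format == "geojson":
        features = []
        for a in annots:
            rings = [np.asarray(p, float).tolist() for p in a.polygons]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "MultiPolygon", "coordinates": [[r] for r in rings]},
                    "properties": {"name": a.name, "source_layer": a.source_layer},
                }
            )
        path.write_text(
            json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
        )
    elif format == "label_mask_png":
        if not annots:
            raise ValueError("no annotations to write")
        shape = annots[0].mask.shape
        label = np.zeros(shape, dtype=np.uint16)
        rows = []
        for code, a in enumerate(annots, start=1):
            if np.any(label[a.mask] != 0):
                raise ValueError(
                    f"ROI {a.name!r} overlaps a previously coded ROI; "
                    "label-mask codes would collide"
                )
            label[a.mask] = code
            rows.append((code, a.name))
        PILImage.fromarray(label).save(path)
        with open(path.with_name(path.stem + "_labels.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "name"])
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown annotation format {format!r}")


def read_annotations(path: str | Path, shape: tuple[int, int] | None = None) -> list[RoiAnnotation]:
    """Read annotations back from GeoJSON or a label-mask PNG + sidecar CSV."""
    path = Path(path)
    if path.suffix.lower() == ".geojson" or path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        out = []
        for feat in data["features"]:
            rings = [np.asarray(r[0], float) for r in feat["geometry"]["coordinates"]]
            props = feat["properties"]
            mask = (
                mask_from_polygon(rings, shape) if shape is not None else np.zeros((2, 2), bool)
            )
            out.append(
                RoiAnnotation(
                    name=props["name"],
                    mask=mask,
                    polygons=rings,
                    source_layer=int(props.get("source_layer", -1)),
                )
            )
        return out
    label = np.asarray(PILImage.open(path))
    names = {}
    with open(path.with_name(path.stem + "_labels.csv")) as fh:
        for row in csv.DictReader(fh):
            names[int(row["code"])] = row["name"]
    return [
        roi_from_mask(names[code], label == code) for code in sorted(names)
    ]


# ---------------------------------------------------------------------------
# template stacks
# ---------------------------------------------------------------------------


@dataclass
class TemplateStack:
    """Ordered reference layers: ``(layer_id, image, {roi_name: mask})``."""

    layers: list[tuple[int, Image, dict[str, np.ndarray]]]

    def __post_init__(self) -> None:
        ids = [lid for lid, _, _ in self.layers]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("layer_ids must be strictly increasing")
        for lid, img, masks in self.layers:
            for name, m in masks.items():
                if m.shape != img.shape:
                    raise ValueError(f"mask {name!r} of layer {lid} has mismatched shape")

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def layer_ids(self) -> list[int]:
        return [lid for lid, _, _ in self.layers]

    def layer(self, layer_id: int) -> tuple[Image, dict[str, np.ndarray]]:
        for lid, img, masks in self.layers:
            if lid == layer_id:
                return img, masks
        raise KeyError(f"no layer {layer_id}")


_LAYER_RE = re.compile(r"^layer_(\d+)\.png$")
_MASK_RE = re.compile(r"^layer_(\d+)_roi_(.+)\.png$")


def write_stack(stack: TemplateStack, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for lid, img, masks in stack.layers:
        write_image(img, directory / f"layer_{lid:03d}.png")
        for name, m in masks.items():
            write_image(m.astype(float), directory / f"layer_{lid:03d}_roi_{name}.png")


def read_stack(directory: str | Path) -> TemplateStack:
    """Read ``layer_NNN.png`` images and ``layer_NNN_roi_<name>.png`` masks."""
    directory = Path(directory)
    images: dict[int, Image] = {}
    masks: dict[int, dict[str, np.ndarray]] = {}
    for p in sorted(directory.iterdir()):
        if m := _LAYER_RE.match(p.name):
            images[int(m.group(1))] = read_image(p)
        elif m := _MASK_RE.match(p.name):
            masks.setdefault(int(m.group(1)), {})[m.group(2)] = read_image(p).pixels > 0.5
    if not images:
        raise IOError(f"no layer images found in {directory}")
    return TemplateStack(
        [(lid, images[lid], masks.get(lid, {})) for lid in sorted(images)]
    )
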