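"""Synthetic brains, multi-brain slides, template stacks and ground-truth
deformations.

The generator emulates the study conditions every downstream stage is built
for: light-background slides carrying a grid of dark, textured, slightly
asymmetric tissue sections, some grid positions empty, thin hand-written
note scribbles off-tissue, and a reference template stack obtained by
morphing one base section along a monotone 1-parameter shape family so that
"within +-k layers" matching accuracy is meaningful. Every output is a pure
function of (parameters, seed); all randomness flows through one explicit
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from skimage.feature import peak_local_max

from .core import Image, PointSet
from .register import (
    DisplacementField,
    SimilarityTransform,
    jacobian_map,
    warp_image,
    warp_points,
)
from .slide_io import MetadataTable, RoiAnnotation, TemplateStack, roi_from_mask

__all__ = [
    "BrainShapeParams",
    "PhantomBrain",
    "PlacedBrain",
    "PhantomSlide",
    "GroundTruthWarp",
    "make_brain",
    "make_stack",
    "make_slide",
    "make_elastic_warp",
    "deform",
]

# intensity conventions of the synthetic slides (light background, darker
# tissue, near-black ink), fractions of full scale
BACKGROUND = 0.97
NOTE_INK = 0.08


@dataclass
class BrainShapeParams:
    """Geometry of one synthetic coronal section.

    Sizes are fractions of the (square) image side; the morph parameter
    ``t`` in [0, 1] moves the section monotonically through the shape family
    used to build template stacks.
    """

    size: int = 128
    rx: float = 0.34  # horizontal semi-axis, fraction of side
    ry: float = 0.26  # vertical semi-axis
    wobble: float = 0.06  # boundary perturbation amplitude
    asymmetry: float = 0.12  # left/right radius imbalance
    texture_sigma: float = 2.5  # smoothing of the internal texture, px
    n_landmarks: int = 12
    t: float = 0.0  # morph parameter along the stack family

    def morphed(self, t: float) -> "BrainShapeParams":
        """Shape at position ``t`` of the monotone stack family."""
        return replace(
            self,
            rx=self.rx * (1.0 + 0.28 * t),
            ry=self.ry * (1.0 - 0.18 * t),
            wobble=self.wobble * (1.0 + 0.5 * t),
            t=t,
        )


@dataclass
class PhantomBrain:
    """One synthetic section with ground truth."""

    image: Image
    rois: list[RoiAnnotation]
    landmarks: PointSet
    layer_index: int = 0
    tissue_mask: np.ndarray | None = None


@dataclass
class GroundTruthWarp:
    """A known deformation: a similarity transform or a smooth elastic field.

    ``parameters`` holds a :class:`SimilarityTransform` for kind
    ``similarity`` or a :class:`DisplacementField` for kind
    ``smooth_elastic``; when left None, :func:`deform` generates one from its
    seed. Smooth elastic fields always have positive Jacobian determinant.
    """

    kind: str  # {"similarity", "smooth_elastic"}
    parameters: object | None = None
    max_displacement: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in {"similarity", "smooth_elastic"}:
            raise ValueError(f"unknown warp kind {self.kind!r}")


@dataclass
class PlacedBrain:
    """A brain pasted onto a slide, with its truth carried along."""

    cell: tuple[int, int]
    sample: str
    group: str
    layer_index: int
    origin: tuple[int, int]  # (x0, y0) of the tile in slide coordinates
    tile_shape: tuple[int, int]
    rois: list[RoiAnnotation]  # masks in slide coordinates
    landmarks: PointSet  # slide coordinates
    tissue_mask: np.ndarray  # slide coordinates


@dataclass
class PhantomSlide:
    image: Image
    layout: MetadataTable
    truth_boxes: list  # of detect.DetectedObject
    truth_assignment: dict[int, tuple[int, int]]  # brain index -> layout cell
    brains: list[PlacedBrain] = field(default_factory=list)
    stack: TemplateStack | None = None


# ---------------------------------------------------------------------------
# single brain
# ---------------------------------------------------------------------------


def _tissue_mask(p: BrainShapeParams, rng: np.random.Generator) -> np.ndarray:
    n = p.size
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = (n - 1) / 2.0
    dx = (xx - cx) / n
    dy = (yy - cy) / n
    theta = np.arctan2(dy, dx)
    # low-order boundary wobble + left/right asymmetry
    amp = rng.uniform(0.5, 1.0, 3) * p.wobble
    phase = rng.uniform(0, 2 * np.pi, 3)
    wob = sum(a * np.cos(k * theta + ph) for k, (a, ph) in enumerate(zip(amp, phase), start=2))
    asym = 1.0 + p.asymmetry * (p.t * 0.5 + rng.uniform(0.5, 1.0)) * np.where(dx < 0, 1.0, -1.0) * 0.5
    r = np.sqrt((dx / (p.rx * asym)) ** 2 + (dy / p.ry) ** 2)
    return r < 1.0 + wob


def _ellipse_mask(shape, cx, cy, rx, ry, angle=0.0) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 < 1.0


def make_brain(
    shape_params: BrainShapeParams | None = None,
    seed: int = 0,
    layer_index: int = 0,
) -> PhantomBrain:
    """Generate one textured, asymmetric tissue section with ground truth.

    Returns a section on a light background with two internal ROIs of
    different sizes (a large caudoputamen-like region and a small
    commissure-like one, both slightly darker than surrounding tissue) and
    at least 8 landmark points seated on texture features.
    """
    p = shape_params or BrainShapeParams()
    if p.size < 64:
        raise ValueError("image side length must be >= 64 px")
    rng = np.random.default_rng(seed)
    n = p.size
    tissue = _tissue_mask(p, rng)

    # internal texture: two independent smoothed noise fields blended by the
    # morph parameter so appearance drifts monotonically through the stack
    noise_a = gaussian_filter(rng.standard_normal((n, n)), p.texture_sigma)
    noise_b = gaussian_filter(rng.standard_normal((n, n)), p.texture_sigma)
    tex = (1.0 - 0.6 * p.t) * noise_a + 0.6 * p.t * noise_b
    tex = (tex - tex.mean()) / (tex.std() + 1e-12)
    interior = 0.55 + 0.13 * tex  # mid-gray tissue with visible texture

    # ROIs: positions/sizes in tissue-relative units, drifting with t
    cx = cy = (n - 1) / 2.0
    rx_px = p.rx * n
    ry_px = p.ry * n
    cp = _ellipse_mask(
        (n, n),
        cx - 0.45 * rx_px,
        cy - 0.15 * ry_px,
        (0.34 + 0.06 * p.t) * rx_px,
        (0.42 - 0.05 * p.t) * ry_px,
        angle=0.3,
    )
    aco = _ellipse_mask(
        (n, n),
        cx + (0.40 - 0.10 * p.t) * rx_px,
        cy + 0.38 * ry_px,
        0.22 * rx_px,
        0.28 * ry_px,
        angle=-0.4,
    )
    core = binary_erosion(tissue, iterations=2)
    cp &= core
    aco &= core
    interior = np.where(cp, interior * 0.82, interior)
    interior = np.where(aco, interior * 0.75, interior)

    img = np.full((n, n), BACKGROUND)
    img += rng.normal(0.0, 0.004, (n, n))  # faint scanner noise
    img = np.where(tissue, interior, img)
    img = np.clip(img, 0.0, 1.0)

    # landmarks: strongest texture extrema well inside the tissue
    inner = binary_erosion(tissue, iterations=6)
    sal = np.abs(tex)
    sal[~inner] = 0.0
    peaks = peak_local_max(sal, min_distance=max(4, n // 24), num_peaks=max(p.n_landmarks, 8))
    lm = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)

    rois = [
        roi_from_mask("CP", cp, source_layer=layer_index),
        roi_from_mask("aco", aco, source_layer=layer_index),
    ]
    return PhantomBrain(
        image=Image(img),
        rois=rois,
        landmarks=PointSet(lm),
        layer_index=layer_index,
        tissue_mask=tissue,
    )


# ---------------------------------------------------------------------------
# template stack
# ---------------------------------------------------------------------------


def make_stack(
    n_layers: int = 8,
    seed: int = 0,
    shape_params: BrainShapeParams | None = None,
) -> tuple[TemplateStack, list[PhantomBrain]]:
    """Morph one base section into ``n_layers`` template layers.

    All layers share the base random draws (same seed) so neighbours differ
    only by the monotone shape/texture interpolation; similarity to a query
    therefore falls off with layer distance.
    """
    base = shape_params or BrainShapeParams()
    brains = []
    layers = []
    for i in range(n_layers):
        t = i / max(n_layers - 1, 1)
        b = make_brain(base.morphed(t), seed=seed, layer_index=i)
        brains.append(b)
        layers.append((i, b.image, {r.name: r.mask for r in b.rois}))
    return TemplateStack(layers), brains


# ---------------------------------------------------------------------------
# ground-truth warps
# ---------------------------------------------------------------------------


def make_elastic_warp(
    shape: tuple[int, int],
    max_displacement: float,
    seed: int,
    spacing: float | None = None,
) -> DisplacementField:
    """Random smooth diffeomorphic field with max displacement as requested.

    Low-frequency random B-spline velocity coefficients, scaled so that the
    dense displacement magnitude peaks at ``max_displacement`` pixels; the
    scaling keeps the field well inside the positive-Jacobian regime for the
    coarse spacings used here.
    """
    rng = np.random.default_rng(seed)
    f = DisplacementField.zeros(shape, spacing=spacing or max(shape) / 4.0)
    coeff = rng.standard_normal(f.control_points.shape)
    f = DisplacementField(coeff, f.spacing, shape, diffeomorphic=True)
    mag = float(np.sqrt((f.dense() ** 2).sum(axis=2)).max())
    if mag > 0:
        f = DisplacementField(
            coeff * (max_displacement / mag), f.spacing, shape, diffeomorphic=True
        )
    if float(jacobian_map(f).min()) <= 0:
        raise ValueError("generated field folds; reduce max_displacement")
    return f


def deform(
    image: Image | np.ndarray,
    warp: GroundTruthWarp,
    seed: int = 0,
    cval: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a ground-truth warp; return the warped image and the exact
    dense backward displacement used (shape (H, W, 2), (dx, dy) order).

    The image is resampled by backward mapping with bilinear interpolation:
    ``out(x) = image(x + u(x))``.
    """
    px = image.pixels if isinstance(image, Image) else np.asarray(image, float)
    h, w = px.shape
    if warp.kind == "similarity":
        t = warp.parameters
        if t is None:
            rng = np.random.default_rng(seed)
            t = SimilarityTransform(
                rotation=np.deg2rad(rng.uniform(-10, 10)),
                scale=rng.uniform(0.95, 1.05),
                translation=tuple(rng.uniform(-5, 5, 2)),
                center=((w - 1) / 2.0, (h - 1) / 2.0),
            )
        ys, xs = np.mgrid[0:h, 0:w].astype(float)
        pts = t.inverse().apply(np.stack([xs.ravel(), ys.ravel()], axis=1))
        u = np.stack(
            [pts[:, 0].reshape(h, w) - xs, pts[:, 1].reshape(h, w) - ys], axis=2
        )
        warped = warp_image(px, t, cval=cval)
        return warped, u
    fld = warp.parameters
    if fld is None:
        fld = make_elastic_warp((h, w), warp.max_displacement, seed)
    u = fld.dense()
    if float(jacobian_map(u).min()) <= 0:
        raise ValueError("requested field has non-positive Jacobian determinant")
    warped = warp_image(px, fld, cval=cval)
    return warped, u


# ---------------------------------------------------------------------------
# slides
# ---------------------------------------------------------------------------


def _note_scribble(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """A thin-stroke dark polyline on a transparent (NaN) tile."""
    tile = np.full((height, width), np.nan)
    n_seg = rng.integers(4, 8)
    x = rng.uniform(2, width - 3)
    y = rng.uniform(2, height - 3)
    thick = int(rng.integers(1, 4))  # 1-3 px strokes
    for _ in range(n_seg):
        # endpoints spread over the whole tile: handwriting sweeps rather
        # than piling strokes into a compact blob
        x2 = float(rng.uniform(1, width - 2))
        y2 = float(rng.uniform(1, height - 2))
        length = int(max(abs(x2 - x), abs(y2 - y), 1) * 2)
        xs = np.linspace(x, x2, length)
        ys = np.linspace(y, y2, length)
        for dx in range(thick):
            for dy in range(thick):
                xi = np.clip(xs.astype(int) + dx, 0, width - 1)
                yi = np.clip(ys.astype(int) + dy, 0, height - 1)
                tile[yi, xi] = NOTE_INK
        x, y = x2, y2
    return tile


def make_slide(
    rows: int,
    cols: int,
    missing: set[tuple[int, int]] | None = None,
    n_notes: int = 0,
    seed: int = 0,
    stack: TemplateStack | None = None,
    stack_brains: list[PhantomBrain] | None = None,
    max_deform: float = 6.0,
    allow_empty: bool = False,
    brain_size: int = 128,
    margin: int = 36,
) -> PhantomSlide:
    """Compose a multi-brain slide with full ground truth.

    One jittered, elastically deformed brain occupies every non-missing grid
    cell; ``n_notes`` thin dark scribbles are drawn in an off-tissue strip
    below the grid. When a template stack is supplied (or generated on the
    fly) each placed brain is a deformed copy of one of its layers, so the
    end-to-end truth (layer index, ROI masks, landmark positions, boxes,
    assignment) is known exactly.
    """
    from .detect import DetectedObject  # local import to avoid a cycle

    if rows * cols < 1:
        raise ValueError("grid must have at least one cell")
    missing = set(missing or ())
    all_cells = {(r, c) for r in range(rows) for c in range(cols)}
    if not missing <= all_cells:
        raise ValueError("missing cells outside the grid")
    if missing >= all_cells and not allow_empty:
        raise ValueError("all cells missing; pass allow_empty=True for an empty slide")

    rng = np.random.default_rng(seed)
    if stack is None:
        stack, stack_brains = make_stack(n_layers=6, seed=seed + 1)
    elif stack_brains is None:
        raise ValueError("stack_brains must accompany an explicit stack")

    cell = brain_size + margin
    note_strip = 48 if n_notes > 0 else 0
    sh, sw = rows * cell, cols * cell
    slide = np.full((sh + note_strip, sw), BACKGROUND)
    slide += rng.normal(0.0, 0.004, slide.shape)

    cells_layout: dict[tuple[int, int], tuple[str, str]] = {}
    placed: list[PlacedBrain] = []
    boxes: list[DetectedObject] = []
    assignment: dict[int, tuple[int, int]] = {}

    for r in range(rows):
        for c in range(cols):
            cells_layout[(r, c)] = (f"S{r + 1}{c + 1}", "ctrl" if c % 2 == 0 else "trt")
            if (r, c) in missing:
                continue
            layer = int(rng.integers(0, len(stack)))
            base = stack_brains[layer]
            sub = int(rng.integers(0, 2**31 - 1))

            # elastic deformation in the brain tile frame
            fld = make_elastic_warp((brain_size, brain_size), max_deform, sub)
            tile = warp_image(base.image.pixels, fld, cval=BACKGROUND)
            tmask = warp_image(base.tissue_mask.astype(float), fld, order=0) > 0.5
            roi_masks = {
                roi.name: warp_image(roi.mask.astype(float), fld, order=0) > 0.5
                for roi in base.rois
            }
            lms = warp_points(base.landmarks, fld)

            # similarity jitter applied as part of the paste
            jit = SimilarityTransform(
                rotation=np.deg2rad(rng.uniform(-8, 8)),
                scale=rng.uniform(0.95, 1.05),
                translation=tuple(rng.uniform(-6, 6, 2)),
                center=((brain_size - 1) / 2.0, (brain_size - 1) / 2.0),
            )
            tile = warp_image(tile, jit, cval=BACKGROUND)
            tmask = warp_image(tmask.astype(float), jit, order=0) > 0.5
            roi_masks = {
                k: warp_image(v.astype(float), jit, order=0) > 0.5 for k, v in roi_masks.items()
            }
            lms = warp_points(lms, jit)

            x0 = c * cell + margin // 2
            y0 = r * cell + margin // 2
            region = slide[y0 : y0 + brain_size, x0 : x0 + brain_size]
            region[tmask] = tile[tmask]

            smask = np.zeros(slide.shape, bool)
            smask[y0 : y0 + brain_size, x0 : x0 + brain_size] = tmask
            rois_slide = []
            for name, m in roi_masks.items():
                full = np.zeros(slide.shape, bool)
                full[y0 : y0 + brain_size, x0 : x0 + brain_size] = m
                roi = roi_from_mask(name, full, source_layer=layer)
                rois_slide.append(roi)
            lms_slide = lms + np.array([x0, y0])

            ys_m, xs_m = np.nonzero(smask)
            bbox = (int(xs_m.min()), int(ys_m.min()), int(xs_m.max()) + 1, int(ys_m.max()) + 1)
            cen = (float(xs_m.mean()), float(ys_m.mean()))
            idx = len(placed)
            boxes.append(
                DetectedObject(
                    klass="brain",
                    bbox=bbox,
                    mask=smask[bbox[1] : bbox[3], bbox[0] : bbox[2]],
                    centroid=cen,
                    score=1.0,
                )
            )
            assignment[idx] = (r, c)
            placed.append(
                PlacedBrain(
                    cell=(r, c),
                    sample=cells_layout[(r, c)][0],
                    group=cells_layout[(r, c)][1],
                    layer_index=layer,
                    origin=(x0, y0),
                    tile_shape=(brain_size, brain_size),
                    rois=rois_slide,
                    landmarks=PointSet(lms_slide),
                    tissue_mask=smask,
                )
            )

    # notes in the off-tissue strip under the grid, mutually disjoint so the
    # truth object count is well defined (8-px gaps survive morphological
    # closing in downstream detectors)
    note_intervals: list[tuple[int, int]] = []
    for _ in range(n_notes):
        nw = int(rng.integers(40, 80))
        nh = note_strip - 8
        x0 = int(rng.integers(4, max(sw - nw - 4, 5)))
        for _attempt in range(100):
            if all(x0 + nw + 8 <= a or x0 >= b + 8 for a, b in note_intervals):
                break
            x0 = int(rng.integers(4, max(sw - nw - 4, 5)))
        note_intervals.append((x0, x0 + nw))
        y0 = sh + 4
        tile = _note_scribble(rng, nh, nw)
        ink = ~np.isnan(tile)
        slide[y0 : y0 + nh, x0 : x0 + nw][ink] = tile[ink]
        ys_m, xs_m = np.nonzero(ink)
        bbox = (x0 + int(xs_m.min()), y0 + int(ys_m.min()), x0 + int(xs_m.max()) + 1, y0 + int(ys_m.max()) + 1)
        full = np.zeros(slide.shape, bool)
        full[y0 : y0 + nh, x0 : x0 + nw] = ink
        boxes.append(
            DetectedObject(
                klass="note",
                bbox=bbox,
                mask=full[bbox[1] : bbox[3], bbox[0] : bbox[2]],
                centroid=(float(x0 + xs_m.mean()), float(y0 + ys_m.mean())),
                score=1.0,
            )
        )

    layout = MetadataTable(cells_layout, n_rows=rows, n_cols=cols)
    return PhantomSlide(
        image=Image(np.clip(slide, 0.0, 1.0)),
        layout=layout,
        truth_boxes=boxes,
        truth_assignment=assignment,
        brains=placed,
        stack=stack,
    )
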