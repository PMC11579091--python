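"""Transfer ROIs through computed transforms and score annotation quality.

Quantitative scoring uses the F1/Dice overlap of predicted and reference
binary masks. Qualitative scoring mirrors a two-expert rating workflow:
each annotation is rated 1-5 by adjustment effort, ratings of 1 (none) or 2
(minor) count as "useful", and inter-rater agreement is summarized with
(unweighted) Cohen's kappa, either on the full 5-category scale or after the
useful/not-useful binarization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .register import DisplacementField, SimilarityTransform, warp_image, warp_points
from .slide_io import RoiAnnotation

__all__ = [
    "transfer_roi",
    "f1_mask",
    "usefulness",
    "cohen_kappa",
    "summarize_usefulness",
    "USEFUL_MAX_RATING",
]

# ratings at or below this count as "useful" (no/minor manual adjustment)
USEFUL_MAX_RATING = 2


def transfer_roi(
    roi: RoiAnnotation,
    affine: SimilarityTransform | None,
    field: DisplacementField | None,
    target_shape: tuple[int, int],
) -> RoiAnnotation:
    """Warp a template-layer ROI into the target frame.

    The mask is resampled with nearest-neighbour interpolation through the
    composed transform (affine pre-alignment, then the elastic field in the
    aligned frame); polygon vertices are forward-mapped point-wise and
    re-closed. An ROI that leaves the field of view entirely comes back with
    an empty mask and a warning flag rather than an error.
    """
    steps = [t for t in (affine, field) if t is not None]
    if steps:
        mask = warp_image(roi.mask.astype(float), steps, order=0, shape=target_shape) > 0.5
    else:
        mask = np.zeros(target_shape, bool)
        h = min(target_shape[0], roi.mask.shape[0])
        w = min(target_shape[1], roi.mask.shape[1])
        mask[:h, :w] = roi.mask[:h, :w]
    polys = []
    for ring in roi.polygons:
        warped = warp_points(ring, steps) if steps else np.asarray(ring, float)
        if not np.allclose(warped[0], warped[-1]):
            warped = np.vstack([warped, warped[0]])
        polys.append(warped)
    out = RoiAnnotation(
        name=roi.name, mask=mask, polygons=polys, source_layer=roi.source_layer
    )
    if not mask.any():
        out.warnings.append("warped ROI left the field of view (empty mask)")
    return out


def f1_mask(pred: np.ndarray, truth: np.ndarray) -> float:
    """F1 of binary masks = 2 TP / (2 TP + FP + FN); equals the Dice
    coefficient 2|A∩B| / (|A| + |B|)."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not truth.any():
        raise ValueError("reference mask is empty")
    tp = np.sum(pred & truth)
    fp = np.sum(pred & ~truth)
    fn = np.sum(~pred & truth)
    return float(2 * tp / (2 * tp + fp + fn))


def _validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    required = {"roi_name", "sample_id", "rater_id", "rating"}
    if not required <= set(ratings.columns):
        raise ValueError(f"rating table needs columns {sorted(required)}")
    r = ratings["rating"]
    if not np.issubdtype(r.dtype, np.integer):
        if not np.allclose(r, r.astype(int)):
            raise ValueError("ratings must be integers")
        ratings = ratings.assign(rating=r.astype(int))
    bad = ratings.loc[~ratings["rating"].between(1, 5), "rating"]
    if len(bad):
        raise ValueError(f"ratings outside 1..5: {sorted(bad.unique().tolist())}")
    if ratings.duplicated(["roi_name", "sample_id", "rater_id"]).any():
        raise ValueError("duplicate (roi, sample, rater) entries")
    return ratings


def usefulness(ratings: pd.DataFrame) -> pd.DataFrame:
    """Binarize 1-5 ratings: useful iff rating <= 2 (no/minor adjustment)."""
    ratings = _validate_ratings(ratings)
    out = ratings.copy()
    out["useful"] = out["rating"] <= USEFUL_MAX_RATING
    return out


def cohen_kappa(a, b) -> float:
    """Unweighted Cohen's kappa between two raters' categorical vectors.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of marginal label frequencies. When both raters are constant and
    identical (p_e = 1) agreement is perfect by convention.
    """
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 rated items")
    n = len(a)
    cats = sorted(set(a) | set(b), key=repr)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p_o = float(np.trace(table)) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if abs(1.0 - p_e) < 1e-12:
        if abs(1.0 - p_o) < 1e-12:
            return 1.0
        raise ValueError("chance agreement is 1 but observed agreement is not")
    return float((p_o - p_e) / (1.0 - p_e))


def summarize_usefulness(useful_table: pd.DataFrame) -> dict[str, float]:
    """Per-ROI percentage of (sample, rater) entries rated useful."""
    if len(useful_table) == 0:
        raise ValueError("empty usefulness table")
    if "useful" not in useful_table.columns:
        useful_table = usefulness(useful_table)
    grouped = useful_table.groupby("roi_name")["useful"].mean() * 100.0
    return {str(k): float(v) for k, v in grouped.items()}
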