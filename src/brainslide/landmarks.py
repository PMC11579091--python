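"""Sparse semantic point correspondences between two images.

A classical mutual-best-match ("best buddies") detector: Harris corner
keypoints in both images, zero-mean unit-norm patch descriptors, and a pair
is kept only when each point is the other's highest-correlation match and
the correlation clears a floor. User-supplied landmark files (for example
from an expert) are first-class input through the same
:class:`LandmarkPairs` container; a median-absolute-deviation filter guards
the registration against the occasional wild correspondence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.feature import corner_harris, corner_peaks

from .core import Image, PointSet, as_pixels

__all__ = [
    "LandmarkPairs",
    "CorrespondenceConfig",
    "detect_correspondences",
    "read_landmarks",
    "write_landmarks",
    "filter_pairs",
]


@dataclass
class LandmarkPairs:
    """Paired 2D points: ``p`` in the moving/template image, ``q`` in the
    fixed/target image, with optional per-pair similarity scores."""

    p: PointSet
    q: PointSet
    match_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.p.n != self.q.n:
            raise ValueError(f"pair count mismatch: {self.p.n} vs {self.q.n}")
        self.match_scores = np.asarray(self.match_scores, dtype=float).reshape(-1)
        if self.match_scores.size == 0:
            self.match_scores = np.ones(self.p.n)
        if self.match_scores.size != self.p.n:
            raise ValueError("match_scores length mismatch")

    @property
    def n(self) -> int:
        return self.p.n

    def __len__(self) -> int:
        return self.p.n


@dataclass
class CorrespondenceConfig:
    max_pairs: int = 32
    min_score: float = 0.6
    patch_radius: int = 7
    min_distance: int = 6  # keypoint spacing, px
    n_keypoints: int = 120
    mad_factor: float = 3.5  # outlier rejection in filter_pairs


def _keypoints(px: np.ndarray, cfg: CorrespondenceConfig) -> np.ndarray:
    resp = corner_harris(px, sigma=2.0)
    pts = corner_peaks(
        resp,
        min_distance=cfg.min_distance,
        num_peaks=cfg.n_keypoints,
        exclude_border=cfg.patch_radius + 1,
    )
    return pts  # (row, col)


def _descriptors(px: np.ndarray, pts: np.ndarray, radius: int) -> np.ndarray:
    d = []
    for r, c in pts:
        patch = px[r - radius : r + radius + 1, c - radius : c + radius + 1].ravel()
        patch = patch - patch.mean()
        norm = np.linalg.norm(patch)
        d.append(patch / norm if norm > 1e-12 else patch)
    return np.asarray(d).reshape(len(pts), -1)


def detect_correspondences(
    a: Image | np.ndarray, b: Image | np.ndarray, cfg: CorrespondenceConfig | None = None
) -> LandmarkPairs:
    """Mutual-best patch correspondences between images ``a`` (moving) and
    ``b`` (fixed); deterministic, possibly empty."""
    cfg = cfg or CorrespondenceConfig()
    pa = as_pixels(a)
    pb = as_pixels(b)
    if min(pa.shape + pb.shape) < 64:
        raise ValueError("images must be at least 64x64")
    ka = _keypoints(pa, cfg)
    kb = _keypoints(pb, cfg)
    if len(ka) == 0 or len(kb) == 0:
        return LandmarkPairs(PointSet(), PointSet())
    da = _descriptors(pa, ka, cfg.patch_radius)
    db = _descriptors(pb, kb, cfg.patch_radius)
    sim = da @ db.T  # correlation of normalized patches, in [-1, 1]
    best_ab = sim.argmax(axis=1)
    best_ba = sim.argmax(axis=0)
    pairs = [
        (i, j, sim[i, j])
        for i, j in enumerate(best_ab)
        if best_ba[j] == i and sim[i, j] >= cfg.min_score
    ]
    pairs.sort(key=lambda t: (-t[2], t[0]))
    pairs = pairs[: cfg.max_pairs]
    p = np.array([[ka[i][1], ka[i][0]] for i, _, _ in pairs], float).reshape(-1, 2)
    q = np.array([[kb[j][1], kb[j][0]] for _, j, _ in pairs], float).reshape(-1, 2)
    scores = np.array([s for _, _, s in pairs], float)
    return LandmarkPairs(PointSet(p), PointSet(q), scores)


def filter_pairs(pairs: LandmarkPairs, cfg: CorrespondenceConfig | None = None) -> LandmarkPairs:
    """Drop pairs whose displacement is a MAD outlier.

    The displacement of each pair is compared with the componentwise median
    displacement; pairs deviating by more than ``mad_factor`` times the
    median absolute deviation (of the deviation norms) are removed. With two
    or fewer pairs the set is returned unchanged (MAD undefined).
    """
    cfg = cfg or CorrespondenceConfig()
    if pairs.n <= 2:
        return pairs
    disp = pairs.q.xy - pairs.p.xy
    med = np.median(disp, axis=0)
    dev = np.linalg.norm(disp - med, axis=1)
    mad = float(np.median(dev))
    keep = dev <= cfg.mad_factor * mad + 1e-9  # floor guards the MAD=0 case
    return LandmarkPairs(
        PointSet(pairs.p.xy[keep]), PointSet(pairs.q.xy[keep]), pairs.match_scores[keep]
    )


_COLUMNS = ["x_moving", "y_moving", "x_fixed", "y_fixed"]


def write_landmarks(pairs: LandmarkPairs, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for (xm, ym), (xf, yf) in zip(pairs.p.xy, pairs.q.xy):
            writer.writerow([repr(float(xm)), repr(float(ym)), repr(float(xf)), repr(float(yf))])


def read_landmarks(path: str | Path) -> LandmarkPairs:
    """Read a landmark CSV (columns x_moving, y_moving, x_fixed, y_fixed).

    An empty file yields an empty pair set; a malformed row raises with its
    line number.
    """
    p_rows: list[list[float]] = []
    q_rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and row == _COLUMNS:
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            try:
                vals = [float(c) for c in row]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            p_rows.append(vals[:2])
            q_rows.append(vals[2:])
    return LandmarkPairs(
        PointSet(np.array(p_rows).reshape(-1, 2)), PointSet(np.array(q_rows).reshape(-1, 2))
    )
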