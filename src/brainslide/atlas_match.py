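"""Select the best-matching template-stack layer for a brain image.

The matcher occupies the interface a trained layer classifier would: image
in, layer out. Its deterministic implementation canonicalizes the query and
every template layer to 460 px on the longer side (aspect preserved,
zero-padded to a common frame), coarsely aligns each layer to the query with
a reduced-iteration similarity registration, and scores the aligned pair by
normalized cross-correlation; the argmax layer wins, ties going to the lower
layer id. A ±k tolerance-accuracy metric accompanies it, since neighbouring
coronal layers are anatomically near-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .core import Image, as_pixels
from .register import RegistrationConfig, affine_register, ncc_loss, warp_image
from .slide_io import TemplateStack

__all__ = ["LayerMatch", "MatchConfig", "match_layer", "tolerance_accuracy"]

CANONICAL_SIZE = 460  # longer-side resize applied to query and templates


@dataclass
class LayerMatch:
    layer_id: int
    scores: dict[int, float]  # layer_id -> NCC in [-1, 1]
    method: str = "ncc_after_coarse_affine"


@dataclass
class MatchConfig:
    """Matching knobs: pre-alignment iterations, working resolution and an
    optional restriction of the searched layer-id range."""

    coarse_iters: int = 200
    downsample: int = 4  # working resolution = 460 / downsample
    lr: float = 0.01
    layer_range: tuple[int, int] | None = None  # inclusive (lo, hi)
    invert: bool = False  # set when tissue is darker than background


def _canonical(px: np.ndarray, frame: tuple[int, int]) -> np.ndarray:
    """Resize so the longer side is CANONICAL_SIZE, zero-pad into ``frame``."""
    h, w = px.shape
    s = CANONICAL_SIZE / max(h, w)
    nh, nw = max(int(round(h * s)), 1), max(int(round(w * s)), 1)
    small = resize(px, (nh, nw), order=1, anti_aliasing=True)
    out = np.zeros(frame)
    out[:nh, :nw] = small
    return out


def match_layer(
    brain: Image | np.ndarray, stack: TemplateStack, cfg: MatchConfig | None = None
) -> LayerMatch:
    """Score every stack layer against the brain; best NCC wins."""
    cfg = cfg or MatchConfig()
    if len(stack) == 0:
        raise ValueError("empty template stack")
    query = as_pixels(brain)
    if cfg.invert:
        query = 1.0 - query
    candidates = [
        (lid, img)
        for lid, img, _ in stack.layers
        if cfg.layer_range is None or cfg.layer_range[0] <= lid <= cfg.layer_range[1]
    ]
    if not candidates:
        raise ValueError("layer_range excludes every stack layer")

    frame = (CANONICAL_SIZE, CANONICAL_SIZE)
    q_canon = _canonical(query, frame)
    ds = max(int(cfg.downsample), 1)
    work = (CANONICAL_SIZE // ds, CANONICAL_SIZE // ds)
    q_work = resize(q_canon, work, order=1, anti_aliasing=True)

    reg_cfg = RegistrationConfig(
        lr=cfg.lr, iters=cfg.coarse_iters, try_reflection=False, centroid_init=True
    )
    scores: dict[int, float] = {}
    for lid, img in candidates:
        layer = img.pixels if isinstance(img, Image) else np.asarray(img, float)
        if cfg.invert:
            layer = 1.0 - layer
        l_work = resize(_canonical(layer, frame), work, order=1, anti_aliasing=True)
        res = affine_register(q_work, l_work, reg_cfg)
        aligned = warp_image(l_work, res.transform)
        try:
            scores[lid] = 1.0 - ncc_loss(q_work, aligned)
        except ValueError:  # degenerate warp: no usable correlation
            scores[lid] = -1.0
    best = max(sorted(scores), key=lambda lid: scores[lid])  # ties -> lower id
    return LayerMatch(layer_id=best, scores=scores)


def tolerance_accuracy(pred: list[int], truth: list[int], k: int = 0) -> float:
    """Fraction of predictions within ±k layers of the truth."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    if len(pred) < 1:
        raise ValueError("need at least one prediction")
    if k < 0:
        raise ValueError("k must be >= 0")
    p = np.asarray(pred)
    t = np.asarray(truth)
    return float(np.mean(np.abs(p - t) <= k))
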