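"""Shared containers: 2D intensity images and ordered 2D point sets.

Coordinate convention used throughout the package: pixel coordinates are
0-based with x increasing to the right and y increasing downward. Point sets
store ``(x, y)`` pairs; rasters are indexed ``[row = y, col = x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image", "PointSet", "as_pixels"]


@dataclass
class Image:
    """A 2D grayscale image with intensities in [0, 1].

    Parameters
    ----------
    pixels
        2D float array, intensities in [0, 1]. RGB input is collapsed to
        luminance at load time (see :mod:`brainslide.slide_io`).
    spacing
        Optional physical size of one pixel in micrometres (isotropic).
    """

    pixels: np.ndarray
    spacing: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image must be 2D and at least 2x2, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def as_pixels(image: "Image | np.ndarray") -> np.ndarray:
    """Return the 2D float pixel array of an Image or array-like."""
    if isinstance(image, Image):
        return image.pixels
    px = np.asarray(image, dtype=np.float64)
    if px.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {px.shape}")
    return px


@dataclass
class PointSet:
    """An ordered list of 2D points stored as an (n, 2) array of (x, y)."""

    xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        pts = np.asarray(self.xy, dtype=np.float64).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point set contains non-finite coordinates")
        self.xy = pts

    @property
    def n(self) -> int:
        return self.xy.shape[0]

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.xy)
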