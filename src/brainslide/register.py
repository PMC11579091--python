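"""Two-stage 2D image registration: similarity/affine then diffeomorphic
B-spline elastic, with an optional landmark regularization term.

The elastic stage optimizes the B-spline coefficients of a stationary
velocity field ``v``; the dense displacement used to warp the moving image is
the exponential ``exp(v)`` obtained by scaling and squaring, which keeps the
Jacobian determinant of the map positive everywhere (topology preservation).
The loss is

    Loss = NCC + lambda1 * DF + lambda2 * LRT

where NCC is ``1 - normalized cross-correlation`` of the fixed and warped
images, DF is a diffusion regularizer (mean squared spatial gradient of the
displacement) and LRT is the mean squared Euclidean distance between warped
moving-image landmarks and their fixed-image correspondences. Both stages are
minimized with Adam (default learning rate 0.01, 1000 iterations).

Conventions
-----------
* A :class:`SimilarityTransform` maps points from the moving frame to the
  fixed frame; images are warped by backward mapping through its inverse.
* A :class:`DisplacementField` stores velocity coefficients. Its backward
  dense field ``exp(v)`` is added to output coordinates when warping images;
  its forward dense field ``exp(-v)`` is added to point coordinates when
  warping points. The two are inverse maps of each other.
* Gradients: the affine stage uses central finite differences over its four
  parameters; the elastic stage uses the analytic NCC/diffusion/landmark
  chain rule with the exponential linearized in the backward pass (the loss
  itself is always evaluated exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import PointSet, as_pixels

__all__ = [
    "RegistrationError",
    "SimilarityTransform",
    "DisplacementField",
    "RegistrationConfig",
    "LossBreakdown",
    "AffineResult",
    "ElasticResult",
    "ncc_loss",
    "diffusion",
    "landmark_term",
    "total_loss",
    "affine_register",
    "elastic_register",
    "warp_image",
    "warp_points",
    "jacobian_map",
    "invert_field",
]


class RegistrationError(RuntimeError):
    """Raised when an optimization diverges or violates its contract."""


# ---------------------------------------------------------------------------
# similarity transform
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTransform:
    """Rotation + isotropic scale + optional x-reflection + translation.

    Maps a point ``x`` (moving frame) to ``s * R(theta) @ F @ (x - c) + c + t``
    in the fixed frame, with ``F = diag(-1, 1)`` when ``reflection`` is set.
    """

    rotation: float = 0.0
    scale: float = 1.0
    reflection: bool = False
    translation: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part (acting on (x, y) column vectors)."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        if self.reflection:
            rot = rot @ np.diag([-1.0, 1.0])
        return self.scale * rot

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        c = np.asarray(self.center, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        return (pts - c) @ self.matrix.T + c + t

    def inverse(self) -> "SimilarityTransform":
        # (s R F)^-1 = (1/s) F R(-th) = (1/s) R(+th) F when reflecting,
        # (1/s) R(-th) otherwise; translation maps to -A^-1 t.
        rot_inv = self.rotation if self.reflection else -self.rotation
        inv = SimilarityTransform(
            rotation=rot_inv,
            scale=1.0 / self.scale,
            reflection=self.reflection,
            center=self.center,
        )
        t_inv = -inv.matrix @ np.asarray(self.translation, dtype=np.float64)
        inv.translation = (float(t_inv[0]), float(t_inv[1]))
        return inv

    @staticmethod
    def identity(shape: tuple[int, int] | None = None) -> "SimilarityTransform":
        center = (0.0, 0.0)
        if shape is not None:
            center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
        return SimilarityTransform(center=center)


# ---------------------------------------------------------------------------
# B-spline displacement field
# ---------------------------------------------------------------------------


def _cubic_bspline(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = (4.0 - 6.0 * t[m1] ** 2 + 3.0 * t[m1] ** 3) / 6.0
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


def _bspline_matrix(n: int, spacing: float) -> np.ndarray:
    """Dense (n, n_ctrl) matrix evaluating a cubic B-spline lattice at pixels.

    Control point ``j`` sits at pixel coordinate ``(j - 1) * spacing`` so one
    extra control row/column flanks each image edge.
    """
    n_ctrl = int(np.ceil((n - 1) / spacing)) + 3
    x = np.arange(n) / spacing  # continuous lattice coordinate
    j = np.arange(n_ctrl)
    return _cubic_bspline(x[:, None] - (j[None, :] - 1.0))


def _compose_disp(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Return ``u(x) + w(x + u(x))`` for dense fields of shape (H, W, 2)."""
    h, wd = u.shape[:2]
    ys, xs = np.mgrid[0:h, 0:wd].astype(np.float64)
    cy = ys + u[..., 1]
    cx = xs + u[..., 0]
    out = np.empty_like(u)
    out[..., 0] = u[..., 0] + map_coordinates(w[..., 0], [cy, cx], order=1, mode="nearest")
    out[..., 1] = u[..., 1] + map_coordinates(w[..., 1], [cy, cx], order=1, mode="nearest")
    return out


def _exponentiate(v: np.ndarray, steps: int) -> np.ndarray:
    """Scaling-and-squaring exponential of a stationary velocity field."""
    u = v / (2.0**steps)
    for _ in range(steps):
        u = _compose_disp(u, u)
    return u


def invert_field(u: np.ndarray, iters: int = 30) -> np.ndarray:
    """Numerical inverse of a displacement field by fixed-point iteration.

    Returns ``w`` with ``w(x) ~ -u(x + w(x))``, so that (Id + w) inverts
    (Id + u). Converges for smooth, moderate-magnitude fields.
    """
    w = np.zeros_like(u)
    for _ in range(iters):
        # u evaluated at x + w(x):
        u_at = _compose_disp(w, u) - w
        w = -u_at
    return w


@dataclass
class DisplacementField:
    """B-spline-parameterized displacement, optionally diffeomorphic.

    ``control_points`` holds cubic B-spline coefficients on a coarse lattice
    with ``spacing`` pixels between control points; in diffeomorphic mode they
    parameterize a stationary velocity field whose exponential is the actual
    displacement.
    """

    control_points: np.ndarray  # (Cy, Cx, 2) coefficients, (dx, dy) order
    spacing: float
    shape: tuple[int, int]
    diffeomorphic: bool = True
    squaring_steps: int = 6

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=np.float64)
        if self.control_points.ndim != 3 or self.control_points.shape[2] != 2:
            raise ValueError("control_points must have shape (Cy, Cx, 2)")
        self._cache: dict[str, np.ndarray] = {}

    @staticmethod
    def zeros(
        shape: tuple[int, int],
        spacing: float | None = None,
        diffeomorphic: bool = True,
        squaring_steps: int = 6,
    ) -> "DisplacementField":
        h, w = shape
        if spacing is None:
            spacing = max(h, w) / 16.0
        cy = int(np.ceil((h - 1) / spacing)) + 3
        cx = int(np.ceil((w - 1) / spacing)) + 3
        return DisplacementField(
            np.zeros((cy, cx, 2)), spacing, (h, w), diffeomorphic, squaring_steps
        )

    def _basis(self) -> tuple[np.ndarray, np.ndarray]:
        if "by" not in self._cache:
            self._cache["by"] = _bspline_matrix(self.shape[0], self.spacing)
            self._cache["bx"] = _bspline_matrix(self.shape[1], self.spacing)
        return self._cache["by"], self._cache["bx"]

    def dense_velocity(self) -> np.ndarray:
        """Dense (H, W, 2) field interpolated from the control lattice."""
        if "vel" not in self._cache:
            by, bx = self._basis()
            v = np.empty(self.shape + (2,))
            for k in range(2):
                v[..., k] = by @ self.control_points[..., k] @ bx.T
            self._cache["vel"] = v
        return self._cache["vel"]

    def dense(self) -> np.ndarray:
        """Backward displacement u: images sample at ``x + u(x)``."""
        if "bwd" not in self._cache:
            v = self.dense_velocity()
            self._cache["bwd"] = (
                _exponentiate(v, self.squaring_steps) if self.diffeomorphic else v
            )
        return self._cache["bwd"]

    def dense_forward(self) -> np.ndarray:
        """Forward displacement: points move to ``p + u_fwd(p)``."""
        if "fwd" not in self._cache:
            if self.diffeomorphic:
                v = self.dense_velocity()
                self._cache["fwd"] = _exponentiate(-v, self.squaring_steps)
            else:
                self._cache["fwd"] = invert_field(self.dense())
        return self._cache["fwd"]


# ---------------------------------------------------------------------------
# warp operators
# ---------------------------------------------------------------------------

Transform = "SimilarityTransform | DisplacementField | list | tuple"


def _backward_coords(transform, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Sampling coordinates (xs, ys) implementing the backward map."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    steps = transform if isinstance(transform, (list, tuple)) else [transform]
    # points pass through `steps` in forward order; the backward map applies
    # the inverses in reverse order
    for t in reversed(steps):
        if isinstance(t, SimilarityTransform):
            inv = t.inverse()
            pts = inv.apply(np.stack([xs.ravel(), ys.ravel()], axis=1))
            xs = pts[:, 0].reshape(h, w)
            ys = pts[:, 1].reshape(h, w)
        elif isinstance(t, DisplacementField):
            u = t.dense()
            xs2 = map_coordinates(u[..., 0], [ys, xs], order=1, mode="nearest")
            ys2 = map_coordinates(u[..., 1], [ys, xs], order=1, mode="nearest")
            xs = xs + xs2
            ys = ys + ys2
        else:
            raise TypeError(f"unsupported transform {type(t)!r}")
    return xs, ys


def warp_image(
    image,
    transform,
    order: int = 1,
    cval: float = 0.0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Warp an image by backward mapping; out-of-bounds pixels become ``cval``.

    ``transform`` may be a :class:`SimilarityTransform`, a
    :class:`DisplacementField`, or a list of both meaning "apply in this
    order" (e.g. ``[affine, field]``: affine pre-alignment, then the elastic
    field in the aligned frame). ``shape`` sets the output (fixed-frame)
    grid; by default the input shape is kept.
    """
    px = as_pixels(image)
    xs, ys = _backward_coords(transform, shape or px.shape)
    return map_coordinates(px, [ys, xs], order=order, mode="constant", cval=cval)


def warp_points(points, transform) -> np.ndarray:
    """Forward-map (x, y) points (the inverse of the image backward map)."""
    pts = points.xy if isinstance(points, PointSet) else np.asarray(points, float)
    pts = pts.reshape(-1, 2).astype(np.float64)
    steps = transform if isinstance(transform, (list, tuple)) else [transform]
    for t in steps:
        if isinstance(t, SimilarityTransform):
            pts = t.apply(pts)
        elif isinstance(t, DisplacementField):
            u = t.dense_forward()
            dx = map_coordinates(u[..., 0], [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
            dy = map_coordinates(u[..., 1], [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
            pts = pts + np.stack([dx, dy], axis=1)
        else:
            raise TypeError(f"unsupported transform {type(t)!r}")
    return pts


def jacobian_map(field) -> np.ndarray:
    """Determinant of the spatial Jacobian of (Id + u) by central differences."""
    u = field.dense() if isinstance(field, DisplacementField) else np.asarray(field, float)
    dux_dy, dux_dx = np.gradient(u[..., 0])
    duy_dy, duy_dx = np.gradient(u[..., 1])
    return (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------


def _masked(arr: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    return arr[mask] if mask is not None else arr.ravel()


def ncc_loss(fixed, warped, mask: np.ndarray | None = None) -> float:
    """``1 - NCC`` in [0, 2]; 0 means perfect positive correlation.

    Invariant under positive affine intensity rescaling of either image.
    Raises on zero intensity variance (correlation undefined).
    """
    loss, _ = _ncc_loss_grad(as_pixels(fixed), as_pixels(warped), mask, want_grad=False)
    return loss


def _ncc_loss_grad(
    fixed: np.ndarray,
    warped: np.ndarray,
    mask: np.ndarray | None,
    want_grad: bool = True,
    soft: bool = False,
):
    if fixed.shape != warped.shape:
        raise ValueError("fixed and warped shapes differ")
    f = _masked(fixed, mask).astype(np.float64)
    w = _masked(warped, mask).astype(np.float64)
    f0 = f - f.mean()
    w0 = w - w.mean()
    sf = np.sqrt(np.sum(f0 * f0))
    sw = np.sqrt(np.sum(w0 * w0))
    if sf < 1e-12 or sw < 1e-12:
        if soft:  # inside an optimizer: worst loss instead of an exception
            return 2.0, np.zeros_like(fixed) if want_grad else None
        raise ValueError("zero intensity variance: correlation undefined")
    rho = float(np.sum(f0 * w0) / (sf * sw))
    loss = 1.0 - rho
    if not want_grad:
        return loss, None
    g_flat = -(f0 / (sf * sw) - rho * w0 / (sw * sw))
    grad = np.zeros_like(fixed)
    if mask is not None:
        grad[mask] = g_flat
    else:
        grad = g_flat.reshape(fixed.shape)
    return loss, grad


def diffusion(field) -> float:
    """Mean squared forward-difference gradient of the dense displacement.

    Zero iff the displacement is spatially constant (pure translation incurs
    no penalty).
    """
    u = field.dense() if isinstance(field, DisplacementField) else np.asarray(field, float)
    val, _ = _diffusion_grad(u, want_grad=False)
    return val


def _diffusion_grad(u: np.ndarray, want_grad: bool = True):
    dx = u[:, 1:, :] - u[:, :-1, :]
    dy = u[1:, :, :] - u[:-1, :, :]
    n = dx.size + dy.size
    val = float((np.sum(dx * dx) + np.sum(dy * dy)) / n)
    if not want_grad:
        return val, None
    g = np.zeros_like(u)
    # adjoint of the forward differences
    g[:, 1:, :] += 2.0 * dx / n
    g[:, :-1, :] -= 2.0 * dx / n
    g[1:, :, :] += 2.0 * dy / n
    g[:-1, :, :] -= 2.0 * dy / n
    return val, g


def landmark_term(warped_p, q) -> float:
    """Sum over pairs and dimensions of squared coordinate differences.

    ``warped_p`` are moving-image landmarks after the current transform; ``q``
    their fixed-image correspondences.
    """
    wp = warped_p.xy if isinstance(warped_p, PointSet) else np.asarray(warped_p, float)
    qq = q.xy if isinstance(q, PointSet) else np.asarray(q, float)
    wp = wp.reshape(-1, 2)
    qq = qq.reshape(-1, 2)
    if wp.shape != qq.shape:
        raise ValueError(f"landmark count mismatch: {wp.shape[0]} vs {qq.shape[0]}")
    if wp.shape[0] < 1:
        raise ValueError("need at least one landmark pair")
    return float(np.sum((wp - qq) ** 2))


# ---------------------------------------------------------------------------
# config / results
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Knobs of both registration stages.

    lr / iters are the Adam step size and iteration count (one schedule per
    stage); lambda1 weights the diffusion term and lambda2 the (per-pair
    mean) landmark term, both 0.5 by default; control_spacing defaults to
    max(image side)/16 pixels.
    """

    lr: float = 0.01
    iters: int = 1000
    lambda1: float = 0.5
    lambda2: float = 0.5
    control_spacing: float | None = None
    diffeomorphic: bool = True
    squaring_steps: int = 6
    multiscale_levels: int = 1
    centroid_init: bool = True
    try_reflection: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.iters < 1:
            raise ValueError("iters must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be >= 0")


@dataclass
class LossBreakdown:
    """One logged iteration: total = ncc + lambda1 * df + lambda2 * lrt.

    ``lrt_term`` is the per-pair mean of squared landmark distances (so the
    weight is comparable across landmark counts); ``lrt_raw`` is the
    unnormalized sum.
    """

    ncc_term: float
    df_term: float
    lrt_term: float
    total: float
    lrt_raw: float = 0.0

    @staticmethod
    def combine(
        ncc: float, df: float, lrt: float, cfg: RegistrationConfig, lrt_raw: float = 0.0
    ) -> "LossBreakdown":
        return LossBreakdown(
            ncc_term=ncc,
            df_term=df,
            lrt_term=lrt,
            total=ncc + cfg.lambda1 * df + cfg.lambda2 * lrt,
            lrt_raw=lrt_raw,
        )


@dataclass
class AffineResult:
    transform: SimilarityTransform
    final_loss: float
    trace: list = dataclass_field(default_factory=list)


@dataclass
class ElasticResult:
    field: DisplacementField
    trace: list = dataclass_field(default_factory=list)  # of LossBreakdown

    @property
    def final_loss(self) -> float:
        return self.trace[-1].total if self.trace else float("nan")


def total_loss(fixed, moving, transform, pairs=None, cfg: RegistrationConfig | None = None) -> LossBreakdown:
    """Evaluate the combined loss for an arbitrary transform state.

    Warps ``moving`` (and the moving-side landmarks of ``pairs``) by
    ``transform`` and combines NCC, diffusion and landmark terms with the
    config weights. Without landmarks the LRT term is zero; without an
    elastic field the diffusion term is zero.
    """
    cfg = cfg or RegistrationConfig()
    fixed_px = as_pixels(fixed)
    warped = warp_image(moving, transform)
    ncc = ncc_loss(fixed_px, warped)
    steps = transform if isinstance(transform, (list, tuple)) else [transform]
    fields = [t for t in steps if isinstance(t, DisplacementField)]
    df = sum(diffusion(f) for f in fields)
    lrt = lrt_raw = 0.0
    if pairs is not None and len(pairs.p) > 0:
        wp = warp_points(pairs.p, transform)
        lrt_raw = landmark_term(wp, pairs.q)
        lrt = lrt_raw / len(pairs.p)
    return LossBreakdown.combine(ncc, float(df), lrt, cfg, lrt_raw)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class _Adam:
    """Plain Adam with the conventional beta/epsilon defaults."""

    def __init__(self, shape, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad * grad
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return -self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# affine stage
# ---------------------------------------------------------------------------


def _intensity_centroid(px: np.ndarray) -> np.ndarray:
    w = px - px.min()
    s = w.sum()
    if s < 1e-12:
        return np.array([(px.shape[1] - 1) / 2.0, (px.shape[0] - 1) / 2.0])
    ys, xs = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    return np.array([(w * xs).sum() / s, (w * ys).sum() / s])


def affine_register(
    fixed, moving, cfg: RegistrationConfig | None = None, mask: np.ndarray | None = None
) -> AffineResult:
    """Similarity registration by Adam on (rotation, log-scale, translation).

    Reflection is handled as a discrete two-way restart; the restart with the
    lower final loss wins. Translation is parameterized in units of half the
    image diagonal so one Adam step moves all parameters on comparable
    scales. Initialization is the identity about the image center, optionally
    shifted so the intensity centroids coincide.
    """
    fixed_px = as_pixels(fixed)
    moving_px = as_pixels(moving)
    cfg = cfg or RegistrationConfig()
    h, w = fixed_px.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t_scale = 0.5 * float(np.hypot(h, w))

    t0 = np.zeros(2)
    if cfg.centroid_init:
        t0 = _intensity_centroid(fixed_px) - _intensity_centroid(moving_px)

    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    grid = np.stack([xs.ravel(), ys.ravel()])  # (2, N), (x, y) rows
    f_flat = _masked(fixed_px, mask).astype(np.float64)
    f0 = f_flat - f_flat.mean()
    sf = np.sqrt(np.sum(f0 * f0))
    if sf < 1e-12:
        raise ValueError("fixed image has zero intensity variance")
    mask_flat = mask.ravel() if mask is not None else None

    def build(theta: np.ndarray, refl: bool) -> SimilarityTransform:
        t = t0 + theta[2:] * t_scale
        return SimilarityTransform(
            rotation=float(theta[0]),
            scale=float(np.exp(theta[1])),
            reflection=refl,
            translation=(float(t[0]), float(t[1])),
            center=(float(center[0]), float(center[1])),
        )

    def loss_of(theta: np.ndarray, refl: bool, it: int) -> float:
        # inverse map applied to the pixel grid, vectorized
        a_inv = build(theta, refl).inverse()
        t = t0 + theta[2:] * t_scale
        pts = a_inv.matrix @ (grid - (center + t)[:, None]) + center[:, None]
        warped = map_coordinates(moving_px, [pts[1], pts[0]], order=1)
        if mask_flat is not None:
            warped = warped[mask_flat]
        w0 = warped - warped.mean()
        sw = np.sqrt(np.sum(w0 * w0))
        if sw < 1e-12:
            return 2.0  # degenerate warp: no correlation
        val = 1.0 - float(np.sum(f0 * w0) / (sf * sw))
        if not np.isfinite(val):
            raise RegistrationError(f"non-finite loss at iteration {it}")
        return val

    eps = 1e-3
    best: tuple[float, SimilarityTransform, list[float]] | None = None
    restarts = [False, True] if cfg.try_reflection else [False]
    for refl in restarts:
        theta = np.zeros(4)
        adam = _Adam(4, cfg.lr)
        trace: list[float] = []
        for it in range(cfg.iters):
            base = loss_of(theta, refl, it)
            trace.append(base)
            grad = np.empty(4)
            for k in range(4):
                d = np.zeros(4)
                d[k] = eps
                grad[k] = (loss_of(theta + d, refl, it) - base) / eps
            theta = theta + adam.step(grad)
        final = loss_of(theta, refl, cfg.iters)
        trace.append(final)
        if best is None or final < best[0]:
            best = (final, build(theta, refl), trace)
    assert best is not None
    return AffineResult(transform=best[1], final_loss=best[0], trace=best[2])


# ---------------------------------------------------------------------------
# elastic stage
# ---------------------------------------------------------------------------


def _bilinear_scatter(g: np.ndarray, pts: np.ndarray, vals: np.ndarray) -> None:
    """Deposit per-point 2-vectors into raster ``g`` with bilinear weights."""
    h, w = g.shape[:2]
    for (x, y), v in zip(pts, vals):
        x0 = int(np.clip(np.floor(x), 0, w - 2))
        y0 = int(np.clip(np.floor(y), 0, h - 2))
        fx = np.clip(x - x0, 0.0, 1.0)
        fy = np.clip(y - y0, 0.0, 1.0)
        g[y0, x0] += (1 - fx) * (1 - fy) * v
        g[y0, x0 + 1] += fx * (1 - fy) * v
        g[y0 + 1, x0] += (1 - fx) * fy * v
        g[y0 + 1, x0 + 1] += fx * fy * v


def elastic_register(
    fixed,
    moving,
    init: SimilarityTransform | None = None,
    pairs=None,
    cfg: RegistrationConfig | None = None,
    mask: np.ndarray | None = None,
) -> ElasticResult:
    """Diffeomorphic B-spline elastic registration with optional landmarks.

    ``init`` (typically the affine-stage result) pre-aligns the moving image;
    the field is estimated in that aligned frame. Landmark pairs are given in
    the original frames; their moving-side points are mapped through ``init``
    before optimization. Returns the field and the per-iteration
    :class:`LossBreakdown` trace.

    Raises :class:`RegistrationError` on a non-finite loss, or if the final
    diffeomorphic field has a non-positive Jacobian determinant anywhere.
    """
    fixed_px = as_pixels(fixed)
    moving_px = as_pixels(moving)
    cfg = cfg or RegistrationConfig()
    h, w = fixed_px.shape

    moving_a = warp_image(moving_px, init) if init is not None else moving_px
    p_a = q = None
    n_pairs = 0
    if pairs is not None and len(pairs.p) > 0:
        p_a = warp_points(pairs.p, init) if init is not None else np.asarray(
            pairs.p.xy if isinstance(pairs.p, PointSet) else pairs.p, float
        ).reshape(-1, 2)
        q = pairs.q.xy if isinstance(pairs.q, PointSet) else np.asarray(pairs.q, float)
        q = q.reshape(-1, 2)
        n_pairs = len(q)

    spacing = cfg.control_spacing or max(h, w) / 16.0
    by = _bspline_matrix(h, spacing)
    bx = _bspline_matrix(w, spacing)
    coeff = np.zeros((by.shape[1], bx.shape[1], 2))

    gy_m, gx_m = np.gradient(moving_a)
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    adam = _Adam(coeff.shape, cfg.lr)
    trace: list[LossBreakdown] = []

    for it in range(cfg.iters):
        v = np.empty((h, w, 2))
        for k in range(2):
            v[..., k] = by @ coeff[..., k] @ bx.T
        if cfg.diffeomorphic:
            u_b = _exponentiate(v, cfg.squaring_steps)
            u_f = _exponentiate(-v, cfg.squaring_steps) if n_pairs else None
        else:
            u_b = v
            u_f = -v if n_pairs else None

        cy = ys + u_b[..., 1]
        cx = xs + u_b[..., 0]
        warped = map_coordinates(moving_a, [cy, cx], order=1)
        ncc, g_img = _ncc_loss_grad(fixed_px, warped, mask, soft=True)
        if not np.isfinite(ncc):
            raise RegistrationError(f"non-finite loss at iteration {it}")
        df, g_df = _diffusion_grad(u_b)

        # dL/du (backward field), NCC chain rule: grad image of the moving
        # frame sampled at the warped coordinates
        g_u = np.empty_like(u_b)
        mx = map_coordinates(gx_m, [cy, cx], order=1)
        my = map_coordinates(gy_m, [cy, cx], order=1)
        g_u[..., 0] = g_img * mx
        g_u[..., 1] = g_img * my
        g_u += cfg.lambda1 * g_df

        lrt = lrt_raw = 0.0
        if n_pairs:
            dx = map_coordinates(u_f[..., 0], [p_a[:, 1], p_a[:, 0]], order=1, mode="nearest")
            dy = map_coordinates(u_f[..., 1], [p_a[:, 1], p_a[:, 0]], order=1, mode="nearest")
            wp = p_a + np.stack([dx, dy], axis=1)
            resid = wp - q
            lrt_raw = float(np.sum(resid * resid))
            lrt = lrt_raw / n_pairs
            # forward field = exp(-v): first-order backward pass flips sign
            g_lm = np.zeros_like(g_u)
            _bilinear_scatter(g_lm, p_a, 2.0 * resid / n_pairs)
            g_u -= cfg.lambda2 * g_lm

        trace.append(LossBreakdown.combine(ncc, df, lrt, cfg, lrt_raw))

        # exponential linearized: velocity gradient ~ displacement gradient;
        # then the exact adjoint of the B-spline interpolation
        g_coeff = np.empty_like(coeff)
        for k in range(2):
            g_coeff[..., k] = by.T @ g_u[..., k] @ bx
        coeff = coeff + adam.step(g_coeff)

    out = DisplacementField(
        coeff, spacing, (h, w), cfg.diffeomorphic, cfg.squaring_steps
    )
    if cfg.diffeomorphic:
        jmin = float(jacobian_map(out).min())
        if jmin <= 0:
            raise RegistrationError(
                f"diffeomorphic contract violated: min Jacobian {jmin:.4f} <= 0"
            )
    return ElasticResult(field=out, trace=trace)
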