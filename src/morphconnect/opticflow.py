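"""Horn-Schunck dense optical flow and the 1-fps motion nuisance regressor.

The Horn-Schunck method minimises a global energy combining the brightness
constancy constraint ``Ex*u + Ey*v + Et = 0`` with a quadratic smoothness
penalty weighted by ``alpha**2``.  Derivatives follow the original scheme:
forward differences averaged over the 2x2x2 spatio-temporal cube, with
replicated image edges.  The per-frame-pair flow field is reduced to a
scalar by summing flow magnitudes inside a binary motion mask; one scalar
per 1-s keyframe interval forms the nuisance regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, correlate

from .stimuli import Regressor

__all__ = [
    "FlowField",
    "horn_schunck",
    "hs_energy",
    "flow_mask",
    "flow_total",
    "build_flow_regressor",
]

# averaging kernel of the classic formulation (weights 1/6 edge, 1/12 corner)
_AVG_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12],
     [1 / 6, 0.0, 1 / 6],
     [1 / 12, 1 / 6, 1 / 12]]
)
_QUAD = 0.25 * np.ones((2, 2))


@dataclass
class FlowField:
    """Dense per-pixel velocities (px/frame) for one frame pair."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("flow must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def _derivatives(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ex, Ey, Et averaged over the 2x2x2 cube (replicated edges).

    Axis convention: x = columns (axis 1), y = rows (axis 0).
    """
    kx = np.array([[-1.0, 1.0], [-1.0, 1.0]]) * 0.25
    ky = np.array([[-1.0, -1.0], [1.0, 1.0]]) * 0.25
    ex = correlate(a, kx, mode="nearest") + correlate(b, kx, mode="nearest")
    ey = correlate(a, ky, mode="nearest") + correlate(b, ky, mode="nearest")
    et = correlate(b - a, _QUAD, mode="nearest")
    return ex, ey, et


def horn_schunck(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alpha: float = 1.0,
    n_iter: int = 30,
) -> FlowField:
    """Estimate dense flow from ``frame_a`` to ``frame_b``.

    Jacobi iteration of the Horn-Schunck update from zero initialisation::

        u <- u_bar - Ex (Ex u_bar + Ey v_bar + Et) / (alpha^2 + Ex^2 + Ey^2)

    Parameters
    ----------
    frame_a, frame_b : 2-D float arrays
        Grayscale frames in [0, 1], identical shapes.
    alpha : float
        Smoothness weight (> 0); larger values give smoother fields.
    n_iter : int
        Iteration count (>= 1; 30 matches common practice for small motion).
    """
    frame_a = np.asarray(frame_a, float)
    frame_b = np.asarray(frame_b, float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    if frame_a.ndim != 2:
        raise ValueError("frames must be 2-D grayscale")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    ex, ey, et = _derivatives(frame_a, frame_b)
    denom = alpha ** 2 + ex ** 2 + ey ** 2
    u = np.zeros_like(frame_a)
    v = np.zeros_like(frame_a)
    for _ in range(n_iter):
        u_bar = convolve(u, _AVG_KERNEL, mode="nearest")
        v_bar = convolve(v, _AVG_KERNEL, mode="nearest")
        t = (ex * u_bar + ey * v_bar + et) / denom
        u = u_bar - ex * t
        v = v_bar - ey * t
    return FlowField(u=u, v=v)


def hs_energy(field: FlowField, frame_a: np.ndarray, frame_b: np.ndarray, alpha: float = 1.0) -> float:
    """Horn-Schunck energy: data term plus ``alpha**2`` times smoothness.

    Used to verify that iterations do not increase the objective.
    """
    ex, ey, et = _derivatives(np.asarray(frame_a, float), np.asarray(frame_b, float))
    data = (ex * field.u + ey * field.v + et) ** 2
    gu = np.gradient(field.u)
    gv = np.gradient(field.v)
    smooth = gu[0] ** 2 + gu[1] ** 2 + gv[0] ** 2 + gv[1] ** 2
    return float(np.sum(data) + alpha ** 2 * np.sum(smooth))


def flow_mask(field: FlowField, threshold: float = 1e-3) -> np.ndarray:
    """Binary motion mask: pixels whose flow magnitude exceeds ``threshold``."""
    return field.magnitude() > threshold


def flow_total(field: FlowField, mask: np.ndarray | None = None) -> float:
    """Sum of absolute flow values (magnitudes) within the mask."""
    mag = field.magnitude()
    if mask is None:
        mask = flow_mask(field)
    if mask.shape != mag.shape:
        raise ValueError("mask shape must match flow shape")
    return float(mag[mask].sum())


def build_flow_regressor(
    sequence: np.ndarray,
    fps: float = 24.0,
    fps_bin: float = 1.0,
    alpha: float = 1.0,
    n_iter: int = 30,
    mask_threshold: float = 1e-3,
    normalize: bool = True,
) -> Regressor:
    """Total optical flow per keyframe interval, as a nuisance regressor.

    Flow is estimated between successive keyframes sampled at ``fps_bin``
    (default 1 fps — frame-by-frame estimation is less robust and gains
    nothing for smooth morphs).  Each interval contributes one scalar,
    max-normalised across the run.
    """
    sequence = np.asarray(sequence, float)
    if sequence.ndim != 3:
        raise ValueError("sequence must be (n_frames, H, W)")
    stride = max(int(round(fps / fps_bin)), 1)
    keyframes = sequence[::stride]
    totals = []
    for a, b in zip(keyframes[:-1], keyframes[1:]):
        field = horn_schunck(a, b, alpha=alpha, n_iter=n_iter)
        totals.append(flow_total(field, flow_mask(field, mask_threshold)))
    reg = Regressor("flow", np.asarray(totals), fps=fps_bin)
    return reg.normalize() if normalize else reg
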