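"""Plug-and-play refinement operators C for the eHIO constraint block.

Each operator maps an array to a refined array of the same shape and can be
wrapped in a :class:`~fdpr.core.ConstraintSpec` to act as a penalty (or hard
replacement) during solving.  For complex fields, denoisers can be routed to
the amplitude, the phase, or the real/imaginary parts via
:func:`complex_constraint`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import uniform_filter

from .core import ComplexField

__all__ = [
    "GuidedFilterParams",
    "amplitude_threshold",
    "tv_denoise",
    "guided_filter",
    "hessian_penalty_gradient",
    "support_projection",
    "complex_constraint",
]


@dataclass
class GuidedFilterParams:
    """Window half-size and regularization of the guided filter.

    ``eps`` is in squared-intensity units; larger values smooth more.  The
    defaults (radius 8, eps 0.04) suit twin-image suppression of phase
    structures; smaller eps preserves more tiny structure.
    """

    radius_px: int = 8
    eps: float = 0.04
    guide: np.ndarray | None = None  # None = self-guided

    def __post_init__(self):
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def amplitude_threshold(x, lo: float, hi: float):
    """Clip the amplitude of a complex field to [lo, hi], preserving phase."""
    if lo > hi:
        raise ValueError(f"lo={lo} exceeds hi={hi}")
    if isinstance(x, ComplexField):
        out = x.copy()
        out.values = amplitude_threshold(x.values, lo, hi)
        return out
    v = np.asarray(x, dtype=complex)
    amp = np.abs(v)
    clipped = np.clip(amp, lo, hi)
    safe = np.where(amp > 0, amp, 1.0)
    return np.where(amp > 0, v * (clipped / safe), clipped)


def tv_denoise(frame: np.ndarray, weight: float,
               iterations: int = 20) -> np.ndarray:
    """Approximate ROF proximal step by Chambolle's dual projection.

    Minimizes ``||u - frame||^2 / 2 + weight * TV(u)`` with ``iterations``
    dual updates (step 1/8, forward-difference TV).  ``weight=0`` returns
    the input unchanged.
    """
    if weight < 0:
        raise ValueError("weight must be non-negative")
    f = np.asarray(frame, dtype=float)
    if weight == 0 or iterations <= 0:
        return f.copy()

    def _div(py, px):
        d = np.zeros_like(f)
        d[:-1, :] += py[:-1, :]
        d[1:, :] -= py[:-1, :]
        d[:, :-1] += px[:, :-1]
        d[:, 1:] -= px[:, :-1]
        return d

    py = np.zeros_like(f)
    px = np.zeros_like(f)
    tau = 0.125  # stability bound for the semi-implicit dual update
    for _ in range(iterations):
        u = f - weight * _div(py, px)
        gy = np.zeros_like(f)
        gx = np.zeros_like(f)
        gy[:-1, :] = u[1:, :] - u[:-1, :]
        gx[:, :-1] = u[:, 1:] - u[:, :-1]
        qy = -gy / weight
        qx = -gx / weight
        denom = 1.0 + tau * np.sqrt(qy ** 2 + qx ** 2)
        py = (py + tau * qy) / denom
        px = (px + tau * qx) / denom
    return f - weight * _div(py, px)


def _box(a: np.ndarray, radius: int) -> np.ndarray:
    # zero-padded box mean normalized by the in-window pixel count, so
    # windows at the border average over the valid pixels only
    size = 2 * radius + 1
    ones = np.ones_like(a)
    num = uniform_filter(a, size=size, mode="constant", cval=0.0)
    den = uniform_filter(ones, size=size, mode="constant", cval=0.0)
    return num / den


def guided_filter(frame: np.ndarray, params: GuidedFilterParams) -> np.ndarray:
    """Edge-preserving smoothing by the local linear model of the guide.

    In every box window of side ``2 r + 1``: ``a = cov(g, f) / (var(g) +
    eps)``, ``b = mean(f) - a mean(g)``; the output is ``mean(a) g +
    mean(b)`` with the coefficient means taken over the same windows.
    """
    f = np.asarray(frame, dtype=float)
    if params.radius_px >= min(f.shape) / 2:
        raise ValueError("radius must be smaller than half the frame size")
    g = f if params.guide is None else np.asarray(params.guide, dtype=float)
    r = params.radius_px
    mean_g = _box(g, r)
    mean_f = _box(f, r)
    cov_gf = _box(g * f, r) - mean_g * mean_f
    var_g = _box(g * g, r) - mean_g * mean_g
    a = cov_gf / (var_g + params.eps)
    b = mean_f - a * mean_g
    return _box(a, r) * g + _box(b, r)


def hessian_penalty_gradient(frame: np.ndarray,
                             weight: float) -> tuple[np.ndarray, float]:
    """Gradient and value of the discrete Hessian (curvature) penalty.

    ``penalty = weight * sum(f_xx^2 + 2 f_xy^2 + f_yy^2)`` with second
    differences on interior pixels and forward cross-differences; the
    returned gradient is the discrete biharmonic form (the adjoint stencils
    applied to the difference images).  Affine frames have zero penalty.
    Complex input is treated as two independent real channels.
    """
    if weight < 0:
        raise ValueError("weight must be non-negative")
    f = np.asarray(frame)
    if np.iscomplexobj(f):
        gr, vr = hessian_penalty_gradient(f.real, weight)
        gi, vi = hessian_penalty_gradient(f.imag, weight)
        return gr + 1j * gi, vr + vi
    f = f.astype(float)
    grad = np.zeros_like(f)
    if weight == 0:
        return grad, 0.0
    fyy = f[:-2, :] - 2 * f[1:-1, :] + f[2:, :]
    fxx = f[:, :-2] - 2 * f[:, 1:-1] + f[:, 2:]
    fxy = (f[1:, 1:] - f[1:, :-1]) - (f[:-1, 1:] - f[:-1, :-1])
    value = float(weight * ((fxx ** 2).sum() + (fyy ** 2).sum()
                            + 2 * (fxy ** 2).sum()))
    # adjoints of the stencils, scatter-added back
    grad[:-2, :] += fyy
    grad[1:-1, :] -= 2 * fyy
    grad[2:, :] += fyy
    grad[:, :-2] += fxx
    grad[:, 1:-1] -= 2 * fxx
    grad[:, 2:] += fxx
    gxy = 2 * fxy
    grad[1:, 1:] += gxy
    grad[1:, :-1] -= gxy
    grad[:-1, 1:] -= gxy
    grad[:-1, :-1] += gxy
    return 2 * weight * grad, value


def support_projection(mask: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Hard support constraint: zero everything outside ``mask``."""
    m = np.asarray(mask, dtype=bool)

    def project(x: np.ndarray) -> np.ndarray:
        return np.where(m, x, 0)

    return project


def complex_constraint(denoiser: Callable[[np.ndarray], np.ndarray],
                       component: str = "phase"
                       ) -> Callable[[np.ndarray], np.ndarray]:
    """Lift a real-image denoiser to complex fields.

    ``component`` selects what the denoiser sees: ``phase`` (amplitude kept),
    ``amplitude`` (phase kept), or ``real_imag`` (both channels denoised).
    The phase route suits inline holography, where the twin image lives in
    the phase of a near-unit-amplitude field.
    """
    if component not in ("phase", "amplitude", "real_imag"):
        raise ValueError(f"unknown component {component!r}")

    def apply(x: np.ndarray) -> np.ndarray:
        v = np.asarray(x)
        if not np.iscomplexobj(v):
            return denoiser(v.astype(float))
        if component == "phase":
            return np.abs(v) * np.exp(1j * denoiser(np.angle(v)))
        if component == "amplitude":
            amp = np.abs(v)
            phase = np.where(amp > 0, v / np.where(amp > 0, amp, 1.0),
                             1.0)
            return denoiser(amp) * phase
        return denoiser(v.real) + 1j * denoiser(v.imag)

    return apply
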