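"""Feature extractors Theta and intensity scalings S.

The feature-domain loss compares *features* of the scaled intensity rather
than raw pixels: first-order image gradients (edge features) or multilevel
biorthogonal wavelet detail bands.  Both extractors are linear maps with
explicit adjoints, which is what makes closed-form Wirtinger backprop through
the loss possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .core import FeatureExtractorSpec

__all__ = [
    "FeaturePyramid",
    "scale_intensity",
    "scale_intensity_derivative",
    "gradient_features",
    "gradient_features_adjoint",
    "wavelet_features",
    "wavelet_inverse",
    "wavelet_features_adjoint",
    "extract",
    "extract_backprop",
]


@dataclass
class FeaturePyramid:
    """Ordered stack of real feature tensors with per-tensor loss weights."""

    tensors: list
    level_ids: list
    weights: list = field(default_factory=list)

    def __post_init__(self):
        if not self.tensors:
            raise ValueError("feature pyramid must contain at least one tensor")
        if not self.weights:
            self.weights = [1.0] * len(self.tensors)
        if len(self.weights) != len(self.tensors):
            raise ValueError("weights must match tensors")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")


# ---------------------------------------------------------------------------
# intensity scaling S
# ---------------------------------------------------------------------------

def scale_intensity(frame: np.ndarray, spec: FeatureExtractorSpec) -> np.ndarray:
    """Pointwise, strictly monotone scaling of a non-negative intensity frame."""
    frame = np.asarray(frame, dtype=float)
    if np.any(frame < 0):
        raise ValueError("intensity frame must be non-negative")
    if spec.scaling == "sqrt":
        return np.sqrt(frame + spec.scaling_epsilon)
    if spec.scaling == "log1p":
        return np.log1p(frame)
    return frame.copy()


def scale_intensity_derivative(frame: np.ndarray,
                               spec: FeatureExtractorSpec) -> np.ndarray:
    """dS/dI evaluated pointwise (used by the chain rule in backprop)."""
    frame = np.asarray(frame, dtype=float)
    if spec.scaling == "sqrt":
        return 0.5 / np.sqrt(frame + max(spec.scaling_epsilon, 1e-12))
    if spec.scaling == "log1p":
        return 1.0 / (1.0 + frame)
    return np.ones_like(frame)


# ---------------------------------------------------------------------------
# gradient features (edge extractor)
# ---------------------------------------------------------------------------

def gradient_features(frame: np.ndarray, scheme: str = "forward") -> FeaturePyramid:
    """Horizontal and vertical first differences with replicate boundary.

    The replicate boundary makes the last row/column difference zero, keeping
    the operator linear with the simple negative-divergence adjoint below.
    """
    f = np.asarray(frame, dtype=float)
    gx = np.zeros_like(f)
    gy = np.zeros_like(f)
    if scheme == "forward":
        gx[..., :, :-1] = f[..., :, 1:] - f[..., :, :-1]
        gy[..., :-1, :] = f[..., 1:, :] - f[..., :-1, :]
    elif scheme == "central":
        gx[..., :, 1:-1] = 0.5 * (f[..., :, 2:] - f[..., :, :-2])
        gy[..., 1:-1, :] = 0.5 * (f[..., 2:, :] - f[..., :-2, :])
    else:
        raise ValueError(f"unknown gradient scheme {scheme!r}")
    return FeaturePyramid([gx, gy], ["grad_x", "grad_y"])


def gradient_features_adjoint(pyr_tensors: Sequence[np.ndarray],
                              scheme: str = "forward") -> np.ndarray:
    """Adjoint of :func:`gradient_features` (negative discrete divergence)."""
    gx, gy = pyr_tensors
    out = np.zeros_like(np.asarray(gx, dtype=float))
    if scheme == "forward":
        out[..., :, :-1] -= gx[..., :, :-1]
        out[..., :, 1:] += gx[..., :, :-1]
        out[..., :-1, :] -= gy[..., :-1, :]
        out[..., 1:, :] += gy[..., :-1, :]
    elif scheme == "central":
        out[..., :, 2:] += 0.5 * gx[..., :, 1:-1]
        out[..., :, :-2] -= 0.5 * gx[..., :, 1:-1]
        out[..., 2:, :] += 0.5 * gy[..., 1:-1, :]
        out[..., :-2, :] -= 0.5 * gy[..., 1:-1, :]
    else:
        raise ValueError(f"unknown gradient scheme {scheme!r}")
    return out


# ---------------------------------------------------------------------------
# wavelet features (multiscale extractor)
# ---------------------------------------------------------------------------

def _level_weights(spec: FeatureExtractorSpec, n_levels: int) -> list[float]:
    return [1.0] * (n_levels + 1)


def wavelet_features(frame: np.ndarray,
                     spec: FeatureExtractorSpec) -> FeaturePyramid:
    """Multilevel 2-D DWT of a frame, sub-bands ordered coarse-to-fine.

    Uses the biorthogonal wavelet named in ``spec`` (default ``bior2.2``,
    whose analysis filters have two vanishing moments, so smooth backgrounds
    land almost entirely in the approximation band).
    """
    f = np.asarray(frame, dtype=float)
    max_lv = pywt.dwtn_max_level(f.shape, pywt.Wavelet(spec.wavelet_name))
    if spec.levels > max(max_lv, 1):
        raise ValueError(
            f"levels={spec.levels} exceeds maximum {max_lv} for shape {f.shape}")
    coeffs = pywt.wavedec2(f, spec.wavelet_name, mode=spec.wavelet_mode,
                           level=spec.levels)
    tensors = [coeffs[0]]
    ids = [f"approx_L{spec.levels}"]
    for i, (ch, cv, cd) in enumerate(coeffs[1:]):
        lv = spec.levels - i
        tensors += [ch, cv, cd]
        ids += [f"detail_h_L{lv}", f"detail_v_L{lv}", f"detail_d_L{lv}"]
    return FeaturePyramid(tensors, ids)


def _pyramid_to_coeffs(tensors: Sequence[np.ndarray]):
    coeffs = [tensors[0]]
    for i in range(1, len(tensors), 3):
        coeffs.append(tuple(tensors[i:i + 3]))
    return coeffs


def wavelet_inverse(pyr: FeaturePyramid, spec: FeatureExtractorSpec,
                    shape: tuple[int, int]) -> np.ndarray:
    """Exact inverse of :func:`wavelet_features` (perfect reconstruction)."""
    rec = pywt.waverec2(_pyramid_to_coeffs(pyr.tensors), spec.wavelet_name,
                        mode=spec.wavelet_mode)
    return rec[: shape[0], : shape[1]]


def _adjoint_wavelet(name: str) -> pywt.Wavelet:
    """Wavelet whose synthesis bank realizes the adjoint of analysis.

    For a biorthogonal pair the inverse DWT is *not* the adjoint; the adjoint
    of filtering with the analysis filters is synthesis with those same
    filters time-reversed.
    """
    w = pywt.Wavelet(name)
    dec_lo, dec_hi = np.asarray(w.dec_lo), np.asarray(w.dec_hi)
    rec_lo, rec_hi = np.asarray(w.rec_lo), np.asarray(w.rec_hi)
    bank = (rec_lo[::-1], rec_hi[::-1], dec_lo[::-1], dec_hi[::-1])
    return pywt.Wavelet(name + "_adj", filter_bank=[list(b) for b in bank])


def wavelet_features_adjoint(tensors: Sequence[np.ndarray],
                             spec: FeatureExtractorSpec,
                             shape: tuple[int, int]) -> np.ndarray:
    """Adjoint of the analysis DWT, exact in ``periodization`` mode.

    The solver's backprop path always evaluates wavelet features in
    periodization mode, where the circular extension is itself unitary-ish
    and this filter-bank transpose is the exact adjoint (validated by the
    dot-product test in the suite).
    """
    if spec.wavelet_mode != "periodization":
        raise ValueError("wavelet adjoint requires periodization mode")
    adj = _adjoint_wavelet(spec.wavelet_name)
    rec = pywt.waverec2(_pyramid_to_coeffs(tensors), adj, mode="periodization")
    return rec[: shape[0], : shape[1]]


# ---------------------------------------------------------------------------
# composed extractor
# ---------------------------------------------------------------------------

def extract(frame: np.ndarray, spec: FeatureExtractorSpec) -> FeaturePyramid:
    """Theta(S(frame)): scale the intensity, then extract features."""
    scaled = scale_intensity(frame, spec)
    if spec.kind == "identity":
        return FeaturePyramid([scaled], ["identity"])
    if spec.kind == "gradient":
        return gradient_features(scaled)
    return wavelet_features(scaled, spec)


def extract_backprop(frame: np.ndarray, grad_tensors: Sequence[np.ndarray],
                     spec: FeatureExtractorSpec) -> np.ndarray:
    """Pull a gradient w.r.t. the feature tensors back to the intensity frame.

    Computes ``S'(I) * Theta^T(g)`` — the chain rule through the linear
    extractor and the pointwise scaling.
    """
    if spec.kind == "identity":
        g = np.asarray(grad_tensors[0], dtype=float)
    elif spec.kind == "gradient":
        g = gradient_features_adjoint(grad_tensors)
    else:
        g = wavelet_features_adjoint(grad_tensors, spec, np.asarray(frame).shape)
    return g * scale_intensity_derivative(frame, spec)
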