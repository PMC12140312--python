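"""Shared domain types for feature-domain phase retrieval.

The package models image formation as a chain of linear operators acting on a
complex wavefront, followed by intensity detection.  Everything downstream
(forward models, solvers, baselines) is built from the types defined here.

Conventions
-----------
* Grids are 2-D with **even** dimensions; spectra are DC-centered
  (fftshift-style), and all Fourier transforms are orthonormal so that
  unitary stages have adjoint == inverse.
* Physical units: lengths in micrometres (um), spatial frequencies in 1/um
  (no 2*pi factor), phases in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ComplexField",
    "PupilFunction",
    "ObservationSet",
    "FeatureExtractorSpec",
    "LossSpec",
    "ConstraintSpec",
    "SolverConfig",
    "LinearOperator",
    "PixelShift",
    "SpectrumShift",
    "CropDownsample",
    "ElementwiseMask",
    "FourierTransform",
    "InverseFourier",
    "AngularSpectrumTransfer",
    "OperatorChain",
    "cfft2",
    "cifft2",
    "make_frequency_grid",
    "validate_observation_set",
    "dot_product_test",
]


# ---------------------------------------------------------------------------
# centered orthonormal FFT helpers
# ---------------------------------------------------------------------------

def cfft2(u: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2-D FFT (DC ends up at the grid center)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(u, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def cifft2(u: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfft2`; also its adjoint (unitary)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(u, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def make_frequency_grid(shape: tuple[int, int], pixel_pitch_um: float):
    """DC-centered spatial-frequency coordinates (1/um) for an even grid.

    Returns ``(fy, fx)`` broadcastable arrays with step ``1/(dim*pitch)``
    per axis and frequency exactly 0 at the center pixel ``dim//2``.
    """
    h, w = shape
    if h % 2 or w % 2:
        raise ValueError(f"grid dimensions must be even, got {shape}")
    if pixel_pitch_um <= 0:
        raise ValueError("pixel_pitch_um must be positive")
    fy = np.fft.fftshift(np.fft.fftfreq(h, d=pixel_pitch_um))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(w, d=pixel_pitch_um))[None, :]
    return fy, fx


def _check_even_2d(values: np.ndarray, name: str) -> None:
    if values.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got ndim={values.ndim}")
    if values.shape[0] % 2 or values.shape[1] % 2:
        raise ValueError(f"{name} dimensions must be even, got {values.shape}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ComplexField:
    """A sampled complex wavefront (the unknown of phase retrieval).

    Parameters
    ----------
    values : complex 2-D array
    pixel_pitch_um : sampling interval of this plane, um
    wavelength_um : illumination wavelength, um
    plane : one of ``object``, ``spectrum``, ``detector``
    """

    values: np.ndarray
    pixel_pitch_um: float
    wavelength_um: float
    plane: str = "object"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        _check_even_2d(self.values, "ComplexField.values")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("ComplexField values must be finite")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.plane not in ("object", "spectrum", "detector"):
            raise ValueError(f"unknown plane label {self.plane!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def copy(self) -> "ComplexField":
        return ComplexField(self.values.copy(), self.pixel_pitch_um,
                            self.wavelength_um, self.plane)


@dataclass
class PupilFunction:
    """Complex pupil over the spatial-frequency plane of the objective.

    The ideal pupil is the indicator of the NA disk; its phase encodes
    aberrations.  Amplitude is clamped (default 1.5) during joint recovery
    because an unbounded pupil amplitude is degenerate with the object.
    """

    values: np.ndarray
    na: float
    wavelength_um: float
    cutoff_radius_px: float
    max_amplitude: float = 1.5

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        _check_even_2d(self.values, "PupilFunction.values")
        if not (0 < self.na <= 1.5):
            raise ValueError("numerical aperture must be in (0, 1.5]")

    @classmethod
    def ideal(cls, shape: tuple[int, int], na: float, wavelength_um: float,
              freq_step: float) -> "PupilFunction":
        """Unaberrated pupil: 1 inside the NA cutoff disk, 0 outside.

        ``freq_step`` is the frequency-grid step in 1/um so that the cutoff
        radius in pixels is ``(na/wavelength)/freq_step``.
        """
        cutoff_px = (na / wavelength_um) / freq_step
        yy = np.arange(shape[0])[:, None] - shape[0] // 2
        xx = np.arange(shape[1])[None, :] - shape[1] // 2
        disk = (yy ** 2 + xx ** 2) <= cutoff_px ** 2
        return cls(disk.astype(complex), na, wavelength_um, cutoff_px)

    @property
    def support(self) -> np.ndarray:
        yy = np.arange(self.values.shape[0])[:, None] - self.values.shape[0] // 2
        xx = np.arange(self.values.shape[1])[None, :] - self.values.shape[1] // 2
        return (yy ** 2 + xx ** 2) <= self.cutoff_radius_px ** 2

    def clamp(self) -> None:
        """Clip pupil amplitude in place to ``max_amplitude``."""
        amp = np.abs(self.values)
        over = amp > self.max_amplitude
        if np.any(over):
            self.values[over] *= self.max_amplitude / amp[over]


@dataclass
class ObservationSet:
    """N non-negative intensity frames plus acquisition metadata.

    ``illum`` holds one descriptor per frame: an LED wave-vector ``(ky, kx)``
    in 1/um for FPM, an integer pixel shift for coded ptychography, or a
    propagation distance for holography.
    """

    frames: np.ndarray
    illum: Sequence
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        try:
            frames = np.asarray(self.frames, dtype=float)
            if frames.ndim == 2:
                frames = frames[None]
            self.frames = frames
        except ValueError:
            # ragged frame shapes: keep as a list so validation can report it
            self.frames = [np.asarray(f, dtype=float) for f in self.frames]

    def __len__(self) -> int:
        return len(self.frames)


def validate_observation_set(obs: ObservationSet) -> list[str]:
    """Return one human-readable issue per violated invariant (empty if OK)."""
    issues: list[str] = []
    frames = obs.frames
    if isinstance(frames, np.ndarray):
        if frames.ndim != 3 or frames.shape[0] < 1:
            issues.append("observation set must contain at least one 2-D frame")
        else:
            if np.any(frames < 0):
                bad = np.unique(np.where(frames < 0)[0])
                for n in bad:
                    issues.append(f"negative intensity in frame {n}")
            if not np.all(np.isfinite(frames)):
                issues.append("non-finite intensity values present")
    else:  # ragged list of frames
        shapes = {np.asarray(f).shape for f in frames}
        if len(shapes) > 1:
            issues.append(f"shape mismatch among frames: {sorted(shapes)}")
        for n, f in enumerate(frames):
            if np.any(np.asarray(f) < 0):
                issues.append(f"negative intensity in frame {n}")
    if len(obs.illum) != len(obs):
        issues.append("illumination descriptors do not match frame count")
    for key in ("wavelength_um", "pixel_pitch_um"):
        if key not in obs.meta:
            issues.append(f"missing metadata: {key}")
    return issues


@dataclass
class FeatureExtractorSpec:
    """Feature extractor Theta and intensity-scaling S of the loss.

    ``kind`` selects the extractor (``gradient``, ``wavelet``, ``identity``),
    ``scaling`` the pointwise intensity transform applied first.  ``sqrt``
    scaling is amplitude-like and variance-stabilizing for shot-noise-
    dominated frames and is the default.
    """

    kind: str = "gradient"
    wavelet_name: str = "bior2.2"
    levels: int = 5
    scaling: str = "sqrt"
    scaling_epsilon: float = 1e-9
    wavelet_mode: str = "symmetric"

    def __post_init__(self):
        if self.kind not in ("gradient", "wavelet", "identity"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.scaling not in ("sqrt", "identity", "log1p"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.scaling_epsilon < 0:
            raise ValueError("scaling_epsilon must be non-negative")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("kind", "wavelet_name", "levels", "scaling",
                 "scaling_epsilon", "wavelet_mode")}


@dataclass
class LossSpec:
    """Distance D between feature tensors: l1, l2 or charbonnier.

    Charbonnier, ``sqrt(r**2 + eps**2) - eps``, is the smooth surrogate of l1
    used whenever gradients are required.
    """

    distance: str = "charbonnier"
    charbonnier_epsilon: float = 1e-3
    per_level_weights: Sequence[float] | None = None

    def __post_init__(self):
        if self.distance not in ("l1", "l2", "charbonnier"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.charbonnier_epsilon <= 0:
            raise ValueError("charbonnier_epsilon must be positive")

    def to_dict(self) -> dict:
        return {"distance": self.distance,
                "charbonnier_epsilon": self.charbonnier_epsilon,
                "per_level_weights": (None if self.per_level_weights is None
                                      else list(self.per_level_weights))}


@dataclass
class ConstraintSpec:
    """A plug-and-play refinement operator C with penalty weight.

    ``constraint`` is any callable mapping an array to a refined array of the
    same shape.  During optimization the solver adds the penalty
    ``weight * ||target - C(target)||_p^2`` (C treated as fixed), or replaces
    the target by ``C(target)`` every few iterations in hard mode.
    """

    constraint: Callable[[np.ndarray], np.ndarray]
    weight: float
    target: str = "object"
    norm_order: int = 2
    name: str = ""
    every: int | None = None  # hard-mode cadence; None = solver default

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("constraint weight must be non-negative")
        if self.target not in ("object", "pupil", "probe", "coded_pattern"):
            raise ValueError(f"unknown constraint target {self.target!r}")


@dataclass
class SolverConfig:
    """Iteration, optimizer and logging settings for the solver."""

    optimizer: str = "adam"
    learning_rates: dict = field(default_factory=dict)
    iterations: int = 500
    seed: int = 0
    stop_tol: float = 0.0
    log_every: int = 0
    constraint_mode: str = "penalty"  # or "hard"
    hard_every: int = 10              # cadence for hard replacement mode
    batch_size: int = 0               # 0 = sum over all frames each step
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.optimizer not in ("adam", "yogi", "sgd_momentum", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        for k, v in self.learning_rates.items():
            if v <= 0:
                raise ValueError(f"learning rate for {k!r} must be positive")

    def lr(self, target: str) -> float:
        defaults = {"object": 0.01, "pupil": 0.001, "coded_pattern": 0.01}
        return self.learning_rates.get(target, defaults.get(target, 0.01))


# ---------------------------------------------------------------------------
# linear operators and chains
# ---------------------------------------------------------------------------

class LinearOperator:
    """Base class: a linear map with an explicit adjoint."""

    kind = "abstract"

    def apply(self, u: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def adjoint(self, v: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class PixelShift(LinearOperator):
    """Circular integer-pixel shift in the current plane."""

    kind = "pixel_shift"

    def __init__(self, shift: tuple[int, int]):
        self.shift = (int(shift[0]), int(shift[1]))

    def apply(self, u):
        return np.roll(u, self.shift, axis=(-2, -1))

    def adjoint(self, v):
        return np.roll(v, (-self.shift[0], -self.shift[1]), axis=(-2, -1))


class SpectrumShift(PixelShift):
    """Integer shift of a DC-centered spectrum (illumination tilt)."""

    kind = "fourier_shift"


class CropDownsample(LinearOperator):
    """Central window crop of a spectrum with amplitude scale ``out/in``.

    Cropping a DC-centered spectrum from ``in_shape`` to ``out_shape`` is the
    band-limited downsampling of the image; the ``prod(out)/prod(in)`` energy
    factor is folded in so that an all-ones object yields unit mean intensity
    through an ideal pupil.  ``offset`` displaces the window center (in
    pixels) to select an obliquely illuminated sub-aperture.
    """

    kind = "crop_downsample"

    def __init__(self, in_shape, out_shape, offset=(0, 0)):
        self.in_shape = tuple(in_shape)
        self.out_shape = tuple(out_shape)
        self.offset = (int(offset[0]), int(offset[1]))
        self.scale = np.sqrt(np.prod(out_shape) / np.prod(in_shape))
        for ax in range(2):
            lo = self.in_shape[ax] // 2 + self.offset[ax] - self.out_shape[ax] // 2
            hi = lo + self.out_shape[ax]
            if lo < 0 or hi > self.in_shape[ax]:
                raise ValueError(
                    f"crop window [{lo}:{hi}] outside spectrum of size "
                    f"{self.in_shape[ax]} along axis {ax}; reduce the "
                    "illumination tilt or enlarge the object grid")
        self._slices = tuple(
            slice(self.in_shape[ax] // 2 + self.offset[ax] - self.out_shape[ax] // 2,
                  self.in_shape[ax] // 2 + self.offset[ax] + self.out_shape[ax] // 2)
            for ax in range(2))

    def apply(self, u):
        return u[(..., *self._slices)] * self.scale

    def adjoint(self, v):
        out = np.zeros(v.shape[:-2] + self.in_shape, dtype=complex)
        out[(..., *self._slices)] = v
        return out * self.scale


class ElementwiseMask(LinearOperator):
    """Pointwise multiplication by a fixed complex mask (pupil, coded pattern)."""

    kind = "elementwise_mask"

    def __init__(self, mask: np.ndarray):
        self.mask = np.asarray(mask, dtype=complex)

    def apply(self, u):
        return u * self.mask

    def adjoint(self, v):
        return v * np.conj(self.mask)


class FourierTransform(LinearOperator):
    kind = "fourier"

    def apply(self, u):
        return cfft2(u)

    def adjoint(self, v):
        return cifft2(v)


class InverseFourier(LinearOperator):
    kind = "inverse_fourier"

    def apply(self, u):
        return cifft2(u)

    def adjoint(self, v):
        return cfft2(v)


class AngularSpectrumTransfer(LinearOperator):
    """Free-space propagation as a unitary spectral filter (band-limited).

    Uses the exact transfer phase ``exp(i 2 pi z sqrt(1/lambda^2 - f^2))``
    and zeroes evanescent components; no Fresnel approximation.
    """

    kind = "angular_spectrum"

    def __init__(self, shape, pixel_pitch_um, wavelength_um, distance_um):
        if not np.isfinite(distance_um):
            raise ValueError("propagation distance must be finite")
        fy, fx = make_frequency_grid(shape, pixel_pitch_um)
        f2 = fy ** 2 + fx ** 2
        kz2 = 1.0 / wavelength_um ** 2 - f2
        self.band = kz2 > 0
        kz = np.sqrt(np.clip(kz2, 0, None))
        self.transfer = np.where(self.band,
                                 np.exp(2j * np.pi * distance_um * kz), 0.0)
        self.distance_um = distance_um

    def apply(self, u):
        return cifft2(cfft2(u) * self.transfer)

    def adjoint(self, v):
        return cifft2(cfft2(v) * np.conj(self.transfer))


class OperatorChain(LinearOperator):
    """Ordered composition of linear operators.

    ``ops[0]`` is applied first (the chain acts as ``ops[-1] ... ops[0]``,
    matching the right-to-left product of factorized propagators).
    """

    kind = "chain"

    def __init__(self, ops: Sequence[LinearOperator]):
        self.ops = list(ops)

    def apply(self, u):
        for op in self.ops:
            u = op.apply(u)
        return u

    def adjoint(self, v):
        for op in reversed(self.ops):
            v = op.adjoint(v)
        return v


def dot_product_test(op: LinearOperator, in_shape, out_shape, rng,
                     n_trials: int = 10) -> float:
    """Max relative error of <A u, v> vs <u, A^H v> over random field pairs."""
    worst = 0.0
    for _ in range(n_trials):
        u = rng.standard_normal(in_shape) + 1j * rng.standard_normal(in_shape)
        v = rng.standard_normal(out_shape) + 1j * rng.standard_normal(out_shape)
        lhs = np.vdot(v, op.apply(u))
        rhs = np.vdot(op.adjoint(v), u)
        denom = max(abs(lhs), abs(rhs), 1e-300)
        worst = max(worst, abs(lhs - rhs) / denom)
    return worst
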