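"""Forward optical models for the three supported modalities.

Each modality factorizes its per-frame propagator into a chain of linear
operators (tilt shift, sub-aperture crop, pupil mask, Fourier transform,
angular-spectrum step, coded-pattern mask), followed by intensity detection
``I = |A_n x|^2`` outside the linear chain.

Two surfaces are provided:

* stateless functions (``fpm_forward``, ``coded_ptych_forward``,
  ``inline_holo_forward``, ``angular_spectrum_propagate``) built on explicit
  :class:`~fdpr.core.OperatorChain` objects, and
* model classes (:class:`FpmModel`, :class:`CodedPtychographyModel`,
  :class:`HolographyModel`) that evaluate all frames in a vectorized batch
  and implement the closed-form adjoint (backprop) pass used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    AngularSpectrumTransfer,
    ComplexField,
    CropDownsample,
    ElementwiseMask,
    InverseFourier,
    ObservationSet,
    OperatorChain,
    PixelShift,
    PupilFunction,
    SpectrumShift,
    cfft2,
    cifft2,
)

__all__ = [
    "FpmSystem",
    "LenslessSystem",
    "led_grid_kvectors",
    "angular_spectrum_propagate",
    "fpm_chain",
    "fpm_forward",
    "coded_ptych_forward",
    "inline_holo_forward",
    "FpmModel",
    "CodedPtychographyModel",
    "HolographyModel",
]


# ---------------------------------------------------------------------------
# system descriptions
# ---------------------------------------------------------------------------

@dataclass
class FpmSystem:
    """Geometry of a Fourier-ptychographic acquisition.

    ``camera_pitch_um`` is the detector pixel pitch referred to object space
    (i.e. already divided by the magnification).  The reconstructed object
    grid has ``object_pixels`` samples at pitch ``camera_pitch_um /
    downsample_factor``; high- and low-resolution grids then share the same
    frequency step ``1/(object_pixels * hires_pitch)``.
    """

    object_pixels: int
    objective_na: float
    wavelength_um: float
    camera_pitch_um: float
    led_kvectors: np.ndarray  # (N, 2) as (ky, kx) in 1/um
    downsample_factor: int = 4

    def __post_init__(self):
        self.led_kvectors = np.atleast_2d(np.asarray(self.led_kvectors, float))
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.object_pixels % (2 * self.downsample_factor):
            raise ValueError("object_pixels must be an even multiple of the "
                             "downsample factor")
        ill_na = self.wavelength_um * np.hypot(*self.led_kvectors.T).max()
        if self.objective_na + ill_na > 1.0 + 1e-9:
            raise ValueError("synthetic NA exceeds 1 (non-physical geometry)")

    @property
    def n_leds(self) -> int:
        return self.led_kvectors.shape[0]

    @property
    def lowres_pixels(self) -> int:
        return self.object_pixels // self.downsample_factor

    @property
    def hires_pitch_um(self) -> float:
        return self.camera_pitch_um / self.downsample_factor

    @property
    def freq_step(self) -> float:
        return 1.0 / (self.object_pixels * self.hires_pitch_um)

    @property
    def pupil_cutoff_px(self) -> float:
        return (self.objective_na / self.wavelength_um) / self.freq_step

    def shift_px(self, n: int) -> tuple[int, int]:
        """Integer spectrum shift (pixels) for LED ``n``."""
        ky, kx = self.led_kvectors[n]
        return (int(round(ky / self.freq_step)), int(round(kx / self.freq_step)))

    def ideal_pupil(self) -> PupilFunction:
        h = self.lowres_pixels
        return PupilFunction.ideal((h, h), self.objective_na,
                                   self.wavelength_um, self.freq_step)

    @property
    def synthetic_na(self) -> float:
        ill = self.wavelength_um * np.hypot(*self.led_kvectors.T).max()
        return self.objective_na + ill


def led_grid_kvectors(n_side: int, spacing_um: float, height_um: float,
                      wavelength_um: float) -> np.ndarray:
    """Wave-vectors (1/um, no 2*pi) of a planar square LED array.

    ``k_n = (y_n, x_n) / (lambda * sqrt(x^2 + y^2 + h^2))`` for LED positions
    on an ``n_side x n_side`` grid centered on the optical axis at height
    ``height_um`` below the sample.  Ordered by distance from the axis so
    brightfield LEDs come first.
    """
    idx = np.arange(n_side) - (n_side - 1) / 2.0
    yy, xx = np.meshgrid(idx * spacing_um, idx * spacing_um, indexing="ij")
    r = np.sqrt(xx ** 2 + yy ** 2 + height_um ** 2)
    k = np.stack([yy / (wavelength_um * r), xx / (wavelength_um * r)], axis=-1)
    k = k.reshape(-1, 2)
    order = np.argsort(np.hypot(k[:, 0], k[:, 1]), kind="stable")
    return k[order]


@dataclass
class LenslessSystem:
    """Coded-ptychography geometry: sample -> coded mask -> sensor."""

    sample_to_mask_um: float
    mask_to_sensor_um: float
    coded_pattern: ComplexField
    scan_shifts_px: np.ndarray  # (N, 2) integer (dy, dx)

    def __post_init__(self):
        if self.sample_to_mask_um < 0 or self.mask_to_sensor_um < 0:
            raise ValueError("propagation distances must be non-negative")
        self.scan_shifts_px = np.atleast_2d(
            np.asarray(self.scan_shifts_px, dtype=int))

    @property
    def n_frames(self) -> int:
        return self.scan_shifts_px.shape[0]

    def check_shift(self, n: int, field_shape: tuple[int, int]) -> tuple[int, int]:
        dy, dx = self.scan_shifts_px[n]
        margin = (min(field_shape) // 2) - 1
        if abs(dy) > margin or abs(dx) > margin:
            raise ValueError(
                f"scan shift {(dy, dx)} for frame {n} exceeds the pattern "
                f"margin {margin} px for field shape {field_shape}")
        return int(dy), int(dx)

    def pattern_window(self, field_shape: tuple[int, int]) -> np.ndarray:
        """Central window of the coded pattern matching the field shape."""
        pv = self.coded_pattern.values
        if pv.shape[0] < field_shape[0] or pv.shape[1] < field_shape[1]:
            raise ValueError("coded pattern smaller than the field")
        r0 = pv.shape[0] // 2 - field_shape[0] // 2
        c0 = pv.shape[1] // 2 - field_shape[1] // 2
        return pv[r0:r0 + field_shape[0], c0:c0 + field_shape[1]]


# ---------------------------------------------------------------------------
# stateless forward operations
# ---------------------------------------------------------------------------

def angular_spectrum_propagate(field: ComplexField,
                               distance_um: float) -> ComplexField:
    """Band-limited angular-spectrum free-space propagation.

    Energy of propagating (non-evanescent) components is conserved exactly;
    propagating by ``+z`` then ``-z`` is the identity on the propagating
    band.
    """
    op = AngularSpectrumTransfer(field.shape, field.pixel_pitch_um,
                                 field.wavelength_um, distance_um)
    out = field.copy()
    out.values = op.apply(field.values)
    return out


def fpm_chain(sys: FpmSystem, pupil_values: np.ndarray,
              frame_index: int) -> OperatorChain:
    """Linear part of the FPM forward model for one LED.

    Composition (applied left to right): spectrum shift by the illumination
    tilt, central crop to the low-resolution grid, pupil mask, inverse
    Fourier transform.  Intensity detection is applied outside the chain.
    """
    H = sys.object_pixels
    h = sys.lowres_pixels
    sy, sx = sys.shift_px(frame_index)
    if abs(sy) + h // 2 > H // 2 or abs(sx) + h // 2 > H // 2:
        raise ValueError(
            f"LED {frame_index} shift {(sy, sx)} pushes the {h}x{h} crop "
            f"window outside the {H}x{H} spectrum")
    return OperatorChain([
        SpectrumShift((-sy, -sx)),
        CropDownsample((H, H), (h, h)),
        ElementwiseMask(pupil_values),
        InverseFourier(),
    ])


def fpm_forward(object_spectrum: ComplexField, pupil: PupilFunction,
                sys: FpmSystem, frame_index: int) -> np.ndarray:
    """Predicted low-resolution intensity for one LED illumination."""
    if object_spectrum.shape != (sys.object_pixels, sys.object_pixels):
        raise ValueError("object spectrum does not match system grid")
    chain = fpm_chain(sys, pupil.values, frame_index)
    u = chain.apply(object_spectrum.values)
    return np.abs(u) ** 2


def coded_ptych_forward(obj: ComplexField, sys: LenslessSystem,
                        frame_index: int) -> np.ndarray:
    """Predicted sensor intensity for one scan position of the sample."""
    dy, dx = sys.check_shift(frame_index, obj.shape)
    pattern = sys.pattern_window(obj.shape)
    chain = OperatorChain([
        PixelShift((dy, dx)),
        AngularSpectrumTransfer(obj.shape, obj.pixel_pitch_um,
                                obj.wavelength_um, sys.sample_to_mask_um),
        ElementwiseMask(pattern),
        AngularSpectrumTransfer(obj.shape, obj.pixel_pitch_um,
                                obj.wavelength_um, sys.mask_to_sensor_um),
    ])
    return np.abs(chain.apply(obj.values)) ** 2


def inline_holo_forward(obj: ComplexField, distance_um: float) -> np.ndarray:
    """Predicted single-shot inline hologram of an object exit wave."""
    return np.abs(angular_spectrum_propagate(obj, distance_um).values) ** 2


# ---------------------------------------------------------------------------
# vectorized solver-facing models
# ---------------------------------------------------------------------------

class FpmModel:
    """Batch FPM forward model with closed-form adjoint backprop.

    Parameters are ``object`` (the high-resolution object *spectrum*, stored
    DC-centered) and optionally ``pupil`` (complex low-resolution pupil grid)
    when ``learn_pupil`` is set.
    """

    def __init__(self, sys: FpmSystem, learn_pupil: bool = True,
                 pupil: PupilFunction | None = None):
        self.sys = sys
        self.learn_pupil = learn_pupil
        self.pupil = pupil if pupil is not None else sys.ideal_pupil()
        H, h = sys.object_pixels, sys.lowres_pixels
        self.scale = h / H
        rows, cols = [], []
        for n in range(sys.n_leds):
            sy, sx = sys.shift_px(n)
            if abs(sy) + h // 2 > H // 2 or abs(sx) + h // 2 > H // 2:
                raise ValueError(f"LED {n} crop window outside the spectrum")
            rows.append(H // 2 + sy - h // 2 + np.arange(h))
            cols.append(H // 2 + sx - h // 2 + np.arange(h))
        self._rows = np.stack(rows)  # (N, h)
        self._cols = np.stack(cols)

    @property
    def targets(self) -> list[str]:
        return ["object", "pupil"] if self.learn_pupil else ["object"]

    def init_params(self, obs: ObservationSet) -> dict:
        """Spectrum of the upsampled root-mean brightfield image, ideal pupil."""
        sys = self.sys
        mean_amp = np.sqrt(np.clip(obs.frames.mean(axis=0), 0, None))
        hi = np.kron(mean_amp, np.ones((sys.downsample_factor,) * 2))
        params = {"object": cfft2(hi.astype(complex))}
        if self.learn_pupil:
            params["pupil"] = self.pupil.values.copy()
        return params

    def _patches(self, X: np.ndarray) -> np.ndarray:
        return X[self._rows[:, :, None], self._cols[:, None, :]]

    def forward(self, params: dict):
        X = params["object"]
        P = params.get("pupil", self.pupil.values)
        patches = self._patches(X)
        u = cifft2(patches * P[None] * self.scale)
        return u, {"patches": patches, "pupil": P}

    def backprop(self, params: dict, grad_fields: np.ndarray, cache: dict) -> dict:
        gm = cfft2(grad_fields) * self.scale
        P = cache["pupil"]
        grads = {"object": np.zeros_like(params["object"])}
        gX = gm * np.conj(P)[None]
        np.add.at(grads["object"],
                  (self._rows[:, :, None], self._cols[:, None, :]), gX)
        if self.learn_pupil:
            grads["pupil"] = (gm * np.conj(cache["patches"])).sum(axis=0)
        return grads

    def intensities(self, params: dict) -> np.ndarray:
        u, _ = self.forward(params)
        return np.abs(u) ** 2

    def project(self, params: dict) -> None:
        """Physical projections after each step: pupil support + amp clamp."""
        if self.learn_pupil and "pupil" in params:
            sup = self.pupil.support
            params["pupil"] *= sup
            amp = np.abs(params["pupil"])
            over = amp > self.pupil.max_amplitude
            params["pupil"][over] *= self.pupil.max_amplitude / amp[over]

    def object_field(self, params: dict) -> ComplexField:
        sys = self.sys
        return ComplexField(cifft2(params["object"]), sys.hires_pitch_um,
                            sys.wavelength_um, plane="object")

    def chain(self, params: dict, frame_index: int) -> OperatorChain:
        return fpm_chain(self.sys, params.get("pupil", self.pupil.values),
                         frame_index)


class CodedPtychographyModel:
    """Coded-ptychography forward model (shifted sample behind a fixed mask).

    Parameters: ``object`` (complex exit wave, spatial domain) and optionally
    ``coded_pattern`` when ``learn_pattern`` is set.
    """

    def __init__(self, sys: LenslessSystem, field_shape: tuple[int, int],
                 pixel_pitch_um: float, wavelength_um: float,
                 learn_pattern: bool = False):
        self.sys = sys
        self.shape = tuple(field_shape)
        self.pitch = pixel_pitch_um
        self.wavelength = wavelength_um
        self.learn_pattern = learn_pattern
        self._p1 = AngularSpectrumTransfer(self.shape, self.pitch,
                                           wavelength_um, sys.sample_to_mask_um)
        self._p2 = AngularSpectrumTransfer(self.shape, self.pitch,
                                           wavelength_um, sys.mask_to_sensor_um)
        self.shifts = [sys.check_shift(n, self.shape)
                       for n in range(sys.n_frames)]

    @property
    def targets(self) -> list[str]:
        return ["object", "coded_pattern"] if self.learn_pattern else ["object"]

    def init_params(self, obs: ObservationSet) -> dict:
        amp = np.sqrt(np.clip(obs.frames.mean(axis=0), 0, None)).astype(complex)
        params = {"object": amp}
        if self.learn_pattern:
            params["coded_pattern"] = np.ones(self.shape, dtype=complex)
        else:
            params.setdefault("coded_pattern", None)
            params.pop("coded_pattern")
        return params

    def forward(self, params: dict):
        o = params["object"]
        pattern = params.get("coded_pattern",
                             self.sys.pattern_window(self.shape))
        shifted = np.stack([np.roll(o, s, axis=(0, 1)) for s in self.shifts])
        q = cifft2(cfft2(shifted) * self._p1.transfer)
        u = cifft2(cfft2(pattern[None] * q) * self._p2.transfer)
        return u, {"q": q, "pattern": pattern}

    def backprop(self, params: dict, grad_fields: np.ndarray, cache: dict) -> dict:
        g2 = cifft2(cfft2(grad_fields) * np.conj(self._p2.transfer))
        grads = {}
        if self.learn_pattern:
            grads["coded_pattern"] = (np.conj(cache["q"]) * g2).sum(axis=0)
        gq = np.conj(cache["pattern"])[None] * g2
        g1 = cifft2(cfft2(gq) * np.conj(self._p1.transfer))
        go = np.zeros(self.shape, dtype=complex)
        for n, s in enumerate(self.shifts):
            go += np.roll(g1[n], (-s[0], -s[1]), axis=(0, 1))
        grads["object"] = go
        return grads

    def intensities(self, params: dict) -> np.ndarray:
        u, _ = self.forward(params)
        return np.abs(u) ** 2

    def project(self, params: dict) -> None:
        pass

    def object_field(self, params: dict) -> ComplexField:
        return ComplexField(params["object"], self.pitch, self.wavelength,
                            plane="object")

    def chain(self, params: dict, frame_index: int) -> OperatorChain:
        pattern = params.get("coded_pattern",
                             self.sys.pattern_window(self.shape))
        return OperatorChain([
            PixelShift(self.shifts[frame_index]),
            self._p1,
            ElementwiseMask(pattern),
            self._p2,
        ])


class HolographyModel:
    """Single-shot (or multi-distance) inline-holography forward model."""

    def __init__(self, shape: tuple[int, int], pixel_pitch_um: float,
                 wavelength_um: float, distances_um: Sequence[float]):
        self.shape = tuple(shape)
        self.pitch = pixel_pitch_um
        self.wavelength = wavelength_um
        self.distances = [float(d) for d in np.atleast_1d(distances_um)]
        self._props = [AngularSpectrumTransfer(self.shape, self.pitch,
                                               wavelength_um, d)
                       for d in self.distances]

    targets = ["object"]

    def init_params(self, obs: ObservationSet) -> dict:
        """Back-propagated root intensity of the first hologram."""
        amp = np.sqrt(np.clip(obs.frames[0], 0, None)).astype(complex)
        back = cifft2(cfft2(amp) * np.conj(self._props[0].transfer))
        return {"object": back}

    def forward(self, params: dict):
        spec = cfft2(params["object"])
        u = np.stack([cifft2(spec * p.transfer) for p in self._props])
        return u, {}

    def backprop(self, params: dict, grad_fields: np.ndarray, cache: dict) -> dict:
        go = np.zeros(self.shape, dtype=complex)
        for n, p in enumerate(self._props):
            go += cifft2(cfft2(grad_fields[n]) * np.conj(p.transfer))
        return {"object": go}

    def intensities(self, params: dict) -> np.ndarray:
        u, _ = self.forward(params)
        return np.abs(u) ** 2

    def project(self, params: dict) -> None:
        pass

    def object_field(self, params: dict) -> ComplexField:
        return ComplexField(params["object"], self.pitch, self.wavelength,
                            plane="object")

    def chain(self, params: dict, frame_index: int) -> OperatorChain:
        return OperatorChain([self._props[frame_index]])
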