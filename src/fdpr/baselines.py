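"""Classical pixel-domain phase-retrieval baselines.

These are the reference algorithms the feature-domain solver is benchmarked
against: Gerchberg-Saxton alternating projections for inline holography,
the extended ptychographic iterative engine (ePIE) for coded ptychography,
embedded pupil recovery (EPRY) for FPM, and its momentum-accelerated
variant (mPIE).  All of them minimize pixel-wise amplitude misfit by
sequential projection-style updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .core import ComplexField, ObservationSet, cfft2, cifft2
from .propagators import (
    AngularSpectrumTransfer,
    CodedPtychographyModel,
    FpmModel,
    FpmSystem,
    LenslessSystem,
)

__all__ = ["BaselineConfig", "BaselineResult", "gs_inline", "epie_coded",
           "epry_fpm", "mpie_fpm"]


@dataclass
class BaselineConfig:
    """Iteration counts and step sizes for the classical algorithms."""

    algorithm: str = "epry"
    iterations: int = 50
    step_object: float = 1.0
    step_probe: float = 1.0
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ("gs", "epie", "epry", "mpie"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not (0 < self.step_object <= 2 and 0 < self.step_probe <= 2):
            raise ValueError("step sizes must be in (0, 2]")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class BaselineResult:
    """Recovered object (+ pupil or pattern) and the per-sweep loss trace."""

    object: ComplexField
    aux: dict = field(default_factory=dict)
    loss_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# Gerchberg-Saxton for inline holography
# ---------------------------------------------------------------------------

def gs_inline(hologram: np.ndarray, distance_um: float,
              config: BaselineConfig,
              constraints: Sequence[Callable[[np.ndarray], np.ndarray]] = (),
              *, wavelength_um: float, pixel_pitch_um: float
              ) -> BaselineResult:
    """Alternating detector-modulus / object-constraint projections.

    Each iteration back-propagates the detector field to the object plane,
    applies the object-plane constraints, propagates forward and replaces
    the detector amplitude by ``sqrt(hologram)`` while keeping the phase.
    The trace records the detector-amplitude L2 error before each
    replacement.
    """
    I = np.asarray(hologram, dtype=float)
    if np.any(I < 0):
        raise ValueError("hologram intensities must be non-negative")
    amp = np.sqrt(I)
    prop = AngularSpectrumTransfer(I.shape, pixel_pitch_um, wavelength_um,
                                   distance_um)
    u_det = amp.astype(complex)
    obj = None
    trace = []
    for _ in range(config.iterations):
        obj = prop.adjoint(u_det)          # back-propagate (-z)
        for c in constraints:
            obj = c(obj)
        u = prop.apply(obj)
        trace.append(float(((np.abs(u) - amp) ** 2).sum()))
        phase = np.where(np.abs(u) > 0, u / np.where(np.abs(u) > 0,
                                                     np.abs(u), 1.0), 1.0)
        u_det = amp * phase
    if obj is None:
        obj = prop.adjoint(u_det)
    return BaselineResult(
        object=ComplexField(obj, pixel_pitch_um, wavelength_um),
        aux={"detector_field": u_det},
        loss_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# ePIE for coded ptychography
# ---------------------------------------------------------------------------

def epie_coded(observation: ObservationSet, sys: LenslessSystem,
               config: BaselineConfig, learn_pattern: bool = True,
               init: dict | None = None) -> BaselineResult:
    """Sequential ePIE updates of the sample and the coded pattern.

    Per frame: propagate the shifted object to the mask, form the exit wave
    with the pattern, propagate to the sensor, replace the amplitude with
    the measurement, and distribute the back-propagated residual to the
    pattern and the object with the conjugate-weighted ePIE rule.
    """
    shifts = [tuple(s) for s in sys.scan_shifts_px]
    if len(set(shifts)) < 2:
        raise ValueError("ePIE needs at least two distinct scan shifts")
    shape = observation.frames.shape[-2:]
    wavelength = observation.meta["wavelength_um"]
    pitch = observation.meta["pixel_pitch_um"]
    p1 = AngularSpectrumTransfer(shape, pitch, wavelength,
                                 sys.sample_to_mask_um)
    p2 = AngularSpectrumTransfer(shape, pitch, wavelength,
                                 sys.mask_to_sensor_um)
    amps = np.sqrt(np.clip(observation.frames, 0, None))

    if init is None:
        obj = np.sqrt(np.clip(observation.frames.mean(axis=0), 0, None)
                      ).astype(complex)
        pattern = sys.pattern_window(shape).copy() if not learn_pattern \
            else np.ones(shape, dtype=complex)
    else:
        obj = np.array(init["object"], dtype=complex)
        pattern = np.array(init["coded_pattern"], dtype=complex)

    order = np.arange(len(shifts))
    np.random.default_rng(config.seed).shuffle(order)
    trace = []
    for _ in range(config.iterations):
        sweep_err = 0.0
        for n in order:
            s = shifts[n]
            o_s = np.roll(obj, s, axis=(0, 1))
            q = p1.apply(o_s)
            exit_wave = pattern * q
            u = p2.apply(exit_wave)
            au = np.abs(u)
            sweep_err += float(((au - amps[n]) ** 2).sum())
            u_new = amps[n] * np.where(au > 0, u / np.where(au > 0, au, 1.0),
                                       1.0)
            delta = p2.adjoint(u_new - u)
            if learn_pattern:
                pattern = pattern + config.step_probe * np.conj(q) \
                    / max(np.abs(q).max() ** 2, 1e-12) * delta
            gq = config.step_object * np.conj(pattern) \
                / max(np.abs(pattern).max() ** 2, 1e-12) * delta
            obj = obj + np.roll(p1.adjoint(gq), (-s[0], -s[1]), axis=(0, 1))
        trace.append(sweep_err)
    return BaselineResult(
        object=ComplexField(obj, pitch, wavelength),
        aux={"coded_pattern": pattern},
        loss_trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# EPRY / mPIE for Fourier ptychography
# ---------------------------------------------------------------------------

def _epry_run(observation: ObservationSet, sys: FpmSystem,
              config: BaselineConfig, momentum: float,
              init: dict | None) -> BaselineResult:
    model = FpmModel(sys, learn_pupil=True)
    params = init if init is not None else model.init_params(observation)
    X = np.array(params["object"], dtype=complex)
    P = np.array(params["pupil"], dtype=complex)
    support = binary_dilation(model.pupil.support,
                              iterations=max(1, int(0.1 * sys.pupil_cutoff_px)))
    H, h = sys.object_pixels, sys.lowres_pixels
    s = h / H
    windows = [(slice(H // 2 + sy - h // 2, H // 2 + sy + h // 2),
                slice(H // 2 + sx - h // 2, H // 2 + sx + h // 2))
               for sy, sx in (sys.shift_px(n) for n in range(sys.n_leds))]
    amps = np.sqrt(np.clip(observation.frames, 0, None))
    trace = []
    vX = np.zeros_like(X)
    vP = np.zeros_like(P)
    for _ in range(config.iterations):
        X_prev, P_prev = X.copy(), P.copy()
        sweep_err = 0.0
        for n in range(sys.n_leds):
            win = windows[n]
            patch = X[win]
            phi = s * P * patch
            u = cifft2(phi)
            au = np.abs(u)
            sweep_err += float(((au - amps[n]) ** 2).sum())
            u_new = amps[n] * np.where(au > 0, u / np.where(au > 0, au, 1.0),
                                       1.0)
            delta = cfft2(u_new - u)
            X[win] = patch + config.step_object * np.conj(P) \
                / max(np.abs(P).max() ** 2, 1e-12) * delta / s
            P_new = P + config.step_probe * np.conj(s * patch) \
                / max(np.abs(s * patch).max() ** 2, 1e-12) * delta
            P = np.where(support, P_new, 0)
        if momentum > 0:
            # heavy-ball extrapolation on the object spectrum only; momentum
            # on the pupil destabilizes the embedded update
            vX = momentum * vX + (X - X_prev)
            X = X + momentum * vX
        trace.append(sweep_err)
    obj = cifft2(X)
    return BaselineResult(
        object=ComplexField(obj, sys.hires_pitch_um, sys.wavelength_um),
        aux={"pupil": P, "object_spectrum": X},
        loss_trace=np.asarray(trace))


def epry_fpm(observation: ObservationSet, sys: FpmSystem,
             config: BaselineConfig, init: dict | None = None
             ) -> BaselineResult:
    """Embedded pupil recovery: alternating-projection FPM with a pupil
    update confined to the slightly dilated NA disk."""
    if not any(np.hypot(*k) * sys.wavelength_um <= sys.objective_na
               for k in sys.led_kvectors):
        raise ValueError("EPRY needs at least one brightfield LED")
    return _epry_run(observation, sys, config, momentum=0.0, init=init)


def mpie_fpm(observation: ObservationSet, sys: FpmSystem,
             config: BaselineConfig, init: dict | None = None
             ) -> BaselineResult:
    """EPRY sweeps with heavy-ball momentum on object and pupil.

    With ``momentum == 0`` the iterates are bitwise identical to
    :func:`epry_fpm`.
    """
    if not any(np.hypot(*k) * sys.wavelength_um <= sys.objective_na
               for k in sys.led_kvectors):
        raise ValueError("mPIE needs at least one brightfield LED")
    return _epry_run(observation, sys, config, momentum=config.momentum,
                     init=init)
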