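"""Synthetic phantoms and acquisition simulators.

Everything the solvers and baselines are tested on is generated here:
resolution targets, phase disks, cell-like blobs and spoke-wheel phase
objects; Zernike pupil aberrations; and full synthetic acquisitions for the
three modalities with the degradations seen in practice (vignetting under
oblique illumination, smooth background, Poisson shot noise, Gaussian read
noise).  All generators are deterministic given their seed, and each
simulator returns a ground-truth record sufficient to regenerate its frames
bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ComplexField, ObservationSet
from .metrics import usaf_linewidth
from .propagators import (
    CodedPtychographyModel,
    FpmModel,
    FpmSystem,
    LenslessSystem,
    angular_spectrum_propagate,
)

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "make_phantom",
    "make_usaf_target",
    "make_zernike_pupil_phase",
    "zernike_basis",
    "apply_degradations",
    "simulate_fpm_dataset",
    "simulate_inline_hologram",
    "simulate_coded_dataset",
]


@dataclass
class PhantomSpec:
    """What object to synthesize: kind, size, amplitude and phase ranges."""

    kind: str = "cell_blobs"
    dims: tuple[int, int] = (128, 128)
    amplitude_range: tuple[float, float] = (0.6, 1.0)
    phase_range_rad: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("usaf_bars", "phase_disk", "cell_blobs",
                             "wheel_phase"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.dims[0] % 2 or self.dims[1] % 2:
            raise ValueError("phantom dims must be even")


@dataclass
class DegradationSpec:
    """Frame degradations applied in fixed order.

    Order: vignette mask, multiplicative polynomial background, Poisson shot
    noise at ``poisson_photons`` per full-scale pixel, additive Gaussian
    noise with sigma ``gaussian_sigma`` (fraction of full scale).  Defaults
    emulate a well-exposed camera: 1e4 photons full scale, 1% read noise.
    """

    vignette: str = "none"           # none | half_plane | shifted_aperture
    vignette_strength: float = 1.0
    background_order: int = 0
    background_amplitude: float = 0.0
    gaussian_sigma: float = 0.01
    poisson_photons: float = 1e4
    seed: int = 0

    def __post_init__(self):
        if self.vignette not in ("none", "half_plane", "shifted_aperture"):
            raise ValueError(f"unknown vignette kind {self.vignette!r}")
        if self.vignette_strength < 0 or self.background_amplitude < 0:
            raise ValueError("degradation strengths must be non-negative")
        if self.poisson_photons is not None and self.poisson_photons <= 0:
            raise ValueError("poisson photon count must be positive")


# ---------------------------------------------------------------------------
# object phantoms
# ---------------------------------------------------------------------------

def _smooth_disk(dims, center, radius, width=1.5):
    yy = np.arange(dims[0])[:, None] - center[0]
    xx = np.arange(dims[1])[None, :] - center[1]
    r = np.hypot(yy, xx)
    return 0.5 * (1 - np.tanh((r - radius) / width))


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(amplitude, phase_rad)`` grids for the requested phantom."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.dims
    a_lo, a_hi = spec.amplitude_range
    p_lo, p_hi = spec.phase_range_rad
    if spec.kind == "phase_disk":
        disk = _smooth_disk(spec.dims, (h / 2, w / 2), min(h, w) / 8)
        return np.full(spec.dims, a_hi), p_lo + (p_hi - p_lo) * disk
    if spec.kind == "wheel_phase":
        yy = np.arange(h)[:, None] - h / 2
        xx = np.arange(w)[None, :] - w / 2
        theta = np.arctan2(yy, xx)
        spokes = 0.5 * (1 + np.sign(np.sin(8 * theta)))
        wheel = spokes * _smooth_disk(spec.dims, (h / 2, w / 2), 0.35 * min(h, w)) \
            * (1 - _smooth_disk(spec.dims, (h / 2, w / 2), 0.06 * min(h, w)))
        return np.full(spec.dims, a_hi), p_lo + (p_hi - p_lo) * wheel
    if spec.kind == "usaf_bars":
        target, _ = make_usaf_target(spec, pitch_um=1.0,
                                     groups=[(7, 1), (7, 3)])
        amp = a_lo + (a_hi - a_lo) * (1 - target)
        return amp, np.zeros(spec.dims)
    # cell_blobs: overlapping soft blobs in amplitude with correlated phase
    amp = np.zeros(spec.dims)
    phs = np.zeros(spec.dims)
    n_blobs = max(6, (h * w) // 1500)
    for _ in range(n_blobs):
        c = rng.uniform([0, 0], [h, w])
        radius = rng.uniform(0.03, 0.09) * min(h, w)
        blob = _smooth_disk(spec.dims, c, radius, width=radius / 2)
        amp += rng.uniform(0.3, 1.0) * blob
        phs += rng.uniform(0.4, 1.0) * blob
    amp = a_lo + (a_hi - a_lo) * (1 - np.clip(amp / max(amp.max(), 1e-12), 0, 1))
    phs = p_lo + (p_hi - p_lo) * phs / max(phs.max(), 1e-12)
    return amp, phs


def make_usaf_target(spec: PhantomSpec, pitch_um: float,
                     groups: Sequence[tuple[int, int]]):
    """Render three-bar USAF-1951 elements on a binary transmission grid.

    Each requested ``(group, element)`` contributes a horizontal and a
    vertical three-bar block whose bar width in pixels follows the USAF
    frequency formula at the given pixel pitch.  Returns the binary grid
    (1 = chrome/foreground) and a geometry table mapping elements to pixel
    extents.
    """
    h, w = spec.dims
    target = np.zeros(spec.dims)
    table = []
    row = 2
    col = 2
    row_height = 0
    for group, element in groups:
        width_um, freq = usaf_linewidth(group, element)
        bw = int(round(width_um / pitch_um))
        if bw < 2:
            raise ValueError(
                f"group {group} element {element}: bar width {width_um:.3f} um "
                f"is under 2 px at pitch {pitch_um} um")
        length = 5 * bw
        block_w = 5 * bw + 1 + length  # horizontal bars + gap + vertical bars
        block_h = max(length, 5 * bw)
        if col + block_w + 2 > w:
            col = 2
            row += row_height + 2 * bw
            row_height = 0
        if row + block_h > h:
            raise ValueError("phantom dims too small for requested elements")
        # three horizontal bars (stacked vertically)
        for i in range(3):
            r0 = row + i * 2 * bw
            target[r0:r0 + bw, col:col + length] = 1.0
        # three vertical bars
        c0 = col + length + 1 + bw
        for i in range(3):
            cc = c0 + i * 2 * bw
            target[row:row + length, cc:cc + bw] = 1.0
        table.append({"group": group, "element": element,
                      "bar_width_px": bw, "line_width_um": width_um,
                      "freq_lpmm": freq, "rows": (row, row + block_h),
                      "cols": (col, col + block_w)})
        col += block_w + 3 * bw
        row_height = max(row_height, block_h)
    return target, table


# ---------------------------------------------------------------------------
# Zernike pupil aberrations
# ---------------------------------------------------------------------------

def _osa_nm(j: int) -> tuple[int, int]:
    n = int(np.ceil((-3 + np.sqrt(9 + 8 * j)) / 2))
    m = 2 * j - n * (n + 2)
    return n, m


def _zernike(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    am = abs(m)
    R = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)))
        R += c * rho ** (n - 2 * k)
    if m >= 0:
        return R * np.cos(am * theta)
    return R * np.sin(am * theta)


def zernike_basis(dims: tuple[int, int], radius_px: float,
                  orders: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """First ``orders`` OSA/ANSI Zernike modes (piston excluded) on a disk.

    Returns ``(basis, disk_mask)`` with ``basis`` of shape
    ``(orders, *dims)``, zero outside the disk of ``radius_px`` pixels
    centered on the grid center.
    """
    yy = (np.arange(dims[0])[:, None] - dims[0] // 2) / radius_px
    xx = (np.arange(dims[1])[None, :] - dims[1] // 2) / radius_px
    rho = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    disk = rho <= 1.0
    if not disk.any():
        raise ValueError("no pixels inside the pupil disk")
    basis = np.stack([_zernike(*_osa_nm(j), rho, theta) * disk
                      for j in range(1, orders + 1)])
    return basis, disk


def make_zernike_pupil_phase(na: float, dims: tuple[int, int],
                             orders: int = 15,
                             coefficients: Sequence[float] | None = None,
                             seed: int | None = None,
                             target_pv_rad: float = 0.0,
                             cutoff_radius_px: float | None = None
                             ) -> np.ndarray:
    """Random (or given) Zernike pupil phase rescaled to an exact peak-to-valley.

    Coefficients default to seeded uniform [-1, 1] draws over the first
    ``orders`` OSA modes (piston excluded).  The combined phase is rescaled
    so its peak-to-valley over the NA disk equals ``target_pv_rad`` exactly;
    all-zero coefficients yield a flat phase.
    """
    if orders < 1:
        raise ValueError("orders must be >= 1")
    if target_pv_rad < 0:
        raise ValueError("target_pv_rad must be non-negative")
    if cutoff_radius_px is None:
        cutoff_radius_px = 0.5 * na * min(dims)
    basis, disk = zernike_basis(dims, cutoff_radius_px, orders)
    if coefficients is None:
        rng = np.random.default_rng(seed)
        coefficients = rng.uniform(-1.0, 1.0, size=orders)
    coefficients = np.asarray(coefficients, dtype=float)
    phase = np.tensordot(coefficients, basis, axes=1)
    vals = phase[disk]
    pv = vals.max() - vals.min()
    if pv == 0:
        return np.zeros(dims)
    if target_pv_rad > 0:
        phase = phase * (target_pv_rad / pv)
    return phase * disk


# ---------------------------------------------------------------------------
# degradations
# ---------------------------------------------------------------------------

def _vignette_mask(shape, kind, strength, k_rel):
    """Angle-dependent vignette for one frame.

    ``k_rel`` is the illumination wave-vector normalized by the objective
    cutoff (0 on axis, >1 for darkfield).  A half-plane vignette darkens the
    half of the frame opposite the illumination tilt; a shifted aperture is
    a circular window whose center displaces linearly with the tilt.
    """
    h, w = shape
    mag = float(np.hypot(*k_rel))
    if kind == "none" or strength == 0 or mag == 0:
        return np.ones(shape)
    u = np.asarray(k_rel) / mag
    yy = np.arange(h)[:, None] - h / 2
    xx = np.arange(w)[None, :] - w / 2
    if kind == "half_plane":
        proj = yy * u[0] + xx * u[1]
        soft = 1.0 / (1.0 + np.exp(proj / 2.0))
        return 1.0 - np.clip(strength, 0, 1) * (1.0 - soft)
    # shifted_aperture: window of radius 0.7 h/2 displaced with the tilt
    radius = 0.35 * min(h, w)
    disp = strength * min(mag, 2.0) * radius
    center = (h / 2 - disp * u[0], w / 2 - disp * u[1])
    return _smooth_disk(shape, center, radius, width=2.0)


def _background(shape, order, amplitude, rng):
    if order <= 0 or amplitude == 0:
        return np.ones(shape)
    yy = np.linspace(-1, 1, shape[0])[:, None]
    xx = np.linspace(-1, 1, shape[1])[None, :]
    bg = np.zeros(shape)
    for py in range(order + 1):
        for px_ in range(order + 1 - py):
            bg += rng.uniform(-1, 1) * yy ** py * xx ** px_
    bg /= max(np.abs(bg).max(), 1e-12)
    return np.clip(1.0 + amplitude * bg, 0.05, None)


def apply_degradations(frames: np.ndarray, degrade: DegradationSpec | None,
                       k_rel: np.ndarray | None = None) -> np.ndarray:
    """Degrade clean frames in the fixed order vignette -> background ->
    Poisson -> Gaussian; returns non-negative frames."""
    if degrade is None:
        return np.asarray(frames, dtype=float)
    frames = np.asarray(frames, dtype=float).copy()
    n = frames.shape[0]
    if k_rel is None:
        k_rel = np.zeros((n, 2))
    rng = np.random.default_rng(degrade.seed)
    for i in range(n):
        frames[i] *= _vignette_mask(frames.shape[1:], degrade.vignette,
                                    degrade.vignette_strength, k_rel[i])
    for i in range(n):
        frames[i] *= _background(frames.shape[1:], degrade.background_order,
                                 degrade.background_amplitude, rng)
    full_scale = max(frames.max(), 1e-12)
    if degrade.poisson_photons:
        frames = rng.poisson(np.clip(frames, 0, None) / full_scale
                             * degrade.poisson_photons) \
            * full_scale / degrade.poisson_photons
    if degrade.gaussian_sigma:
        frames = frames + rng.normal(
            0.0, degrade.gaussian_sigma * full_scale, size=frames.shape)
    return np.clip(frames, 0.0, None)


# ---------------------------------------------------------------------------
# acquisition simulators
# ---------------------------------------------------------------------------

def simulate_fpm_dataset(amplitude: np.ndarray, phase: np.ndarray,
                         sys: FpmSystem,
                         pupil_phase: np.ndarray | None = None,
                         degrade: DegradationSpec | None = None
                         ) -> tuple[ObservationSet, dict]:
    """Low-resolution FPM stack of a known object through an aberrated pupil."""
    amplitude = np.asarray(amplitude, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if amplitude.shape != (sys.object_pixels,) * 2:
        raise ValueError("object grids must match sys.object_pixels")
    obj = amplitude * np.exp(1j * phase)
    pupil = sys.ideal_pupil()
    if pupil_phase is not None:
        pupil.values = pupil.values * np.exp(1j * np.asarray(pupil_phase))
    model = FpmModel(sys, learn_pupil=False, pupil=pupil)
    from .core import cfft2
    frames = model.intensities({"object": cfft2(obj)})
    k_rel = sys.led_kvectors * sys.wavelength_um / sys.objective_na
    frames = apply_degradations(frames, degrade, k_rel=k_rel)
    obs = ObservationSet(frames, list(map(tuple, sys.led_kvectors)),
                         meta={"wavelength_um": sys.wavelength_um,
                               "pixel_pitch_um": sys.camera_pitch_um,
                               "objective_na": sys.objective_na,
                               "modality": "fpm"})
    truth = {"amplitude": amplitude, "phase": phase,
             "pupil": pupil.values.copy(),
             "pupil_phase": pupil_phase, "system": sys, "degrade": degrade}
    return obs, truth


def simulate_inline_hologram(obj: ComplexField, distance_um: float,
                             degrade: DegradationSpec | None = None
                             ) -> tuple[ObservationSet, dict]:
    """Single-shot inline hologram of an object exit wave."""
    holo = np.abs(angular_spectrum_propagate(obj, distance_um).values) ** 2
    frames = apply_degradations(holo[None], degrade)
    obs = ObservationSet(frames, [distance_um],
                         meta={"wavelength_um": obj.wavelength_um,
                               "pixel_pitch_um": obj.pixel_pitch_um,
                               "modality": "holography"})
    truth = {"object": obj.values.copy(), "distance_um": distance_um,
             "degrade": degrade}
    return obs, truth


def make_coded_pattern(dims: tuple[int, int], seed: int,
                       pitch_um: float, wavelength_um: float) -> ComplexField:
    """Random binary-phase (0 or pi) mask with equal fill fractions."""
    rng = np.random.default_rng(seed)
    bits = rng.integers(0, 2, size=dims)
    return ComplexField(np.exp(1j * np.pi * bits), pitch_um, wavelength_um,
                        plane="object")


def simulate_coded_dataset(obj: ComplexField, sample_to_mask_um: float,
                           mask_to_sensor_um: float, n_shifts: int,
                           degrade: DegradationSpec | None = None,
                           seed: int = 0
                           ) -> tuple[ObservationSet, dict, LenslessSystem]:
    """Coded-ptychography stack: shifted sample behind a fixed binary mask.

    Scan positions form a jittered raster of integer pixel shifts.  Returns
    the observations, the ground-truth record, and the system description.
    """
    if n_shifts < 2:
        raise ValueError("need at least 2 scan positions")
    rng = np.random.default_rng(seed)
    pattern = make_coded_pattern(obj.shape, seed + 1, obj.pixel_pitch_um,
                                 obj.wavelength_um)
    side = int(np.ceil(np.sqrt(n_shifts)))
    step = max(2, min(obj.shape) // (4 * side))
    shifts = []
    for i in range(n_shifts):
        base = ((i // side - side // 2) * step, (i % side - side // 2) * step)
        jit = rng.integers(-1, 2, size=2)
        shifts.append((int(base[0] + jit[0]), int(base[1] + jit[1])))
    sys = LenslessSystem(sample_to_mask_um, mask_to_sensor_um, pattern,
                         np.asarray(shifts))
    model = CodedPtychographyModel(sys, obj.shape, obj.pixel_pitch_um,
                                   obj.wavelength_um)
    frames = model.intensities({"object": obj.values,
                                "coded_pattern": pattern.values})
    frames = apply_degradations(frames, degrade)
    obs = ObservationSet(frames, shifts,
                         meta={"wavelength_um": obj.wavelength_um,
                               "pixel_pitch_um": obj.pixel_pitch_um,
                               "modality": "coded"})
    truth = {"object": obj.values.copy(), "pattern": pattern.values.copy(),
             "shifts": shifts, "degrade": degrade, "seed": seed}
    return obs, truth, sys
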