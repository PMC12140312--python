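"""Canned benchmark experiments on synthetic data.

These functions define the study conditions used to validate the solver:
blind pupil-aberration recovery, robustness orderings against the classical
baselines under vignetting and aberrations, and constraint-assisted inline
holography.  Both the test suite and the reproduction script call them, so
the conditions live in exactly one place.
"""

from __future__ import annotations

import numpy as np

from . import constraints as C
from .baselines import BaselineConfig, epry_fpm, gs_inline, mpie_fpm
from .core import (
    ComplexField,
    ConstraintSpec,
    FeatureExtractorSpec,
    LossSpec,
    SolverConfig,
)
from .engine import solve
from .metrics import psnr, pupil_phase_rms_error, ssim
from .phantoms import (
    DegradationSpec,
    PhantomSpec,
    make_phantom,
    make_zernike_pupil_phase,
    simulate_fpm_dataset,
    simulate_inline_hologram,
)
from .propagators import FpmModel, FpmSystem, HolographyModel, \
    led_grid_kvectors

__all__ = [
    "aberrated_fpm_system",
    "blind_aberration_trial",
    "vignette_comparison",
    "aberration_comparison",
    "holography_comparison",
]


def _scaled_psnr(recovered_amp: np.ndarray, reference: np.ndarray) -> float:
    """PSNR after removing the global intensity scale (non-identifiable)."""
    a = float(np.vdot(recovered_amp, reference).real
              / max(np.vdot(recovered_amp, recovered_amp).real, 1e-300))
    return psnr(a * recovered_amp, reference)


def aberrated_fpm_system(object_pixels: int = 128) -> FpmSystem:
    """The 15x15-LED, NA 0.1 geometry used for blind aberration recovery."""
    k = led_grid_kvectors(15, 4000.0, 120000.0, 0.532)
    return FpmSystem(object_pixels=object_pixels, objective_na=0.1,
                     wavelength_um=0.532, camera_pitch_um=1.25,
                     led_kvectors=k, downsample_factor=4)


def blind_aberration_trial(pv_rad: float, seed: int,
                           object_pixels: int = 128,
                           iterations: int = 450) -> dict:
    """Joint object+pupil recovery against a random Zernike aberration.

    Simulates a clean FPM stack through a pupil whose phase is a seeded
    combination of the first 15 OSA Zernike modes rescaled to the requested
    peak-to-valley, then solves blind (ideal-pupil initialization) with
    first-order gradient features.  Returns the pupil-phase RMS error after
    piston/tip/tilt (and conjugate-twin) removal.
    """
    sys_ = aberrated_fpm_system(object_pixels)
    h = sys_.lowres_pixels
    amp, phs = make_phantom(PhantomSpec(kind="cell_blobs",
                                        dims=(object_pixels,) * 2,
                                        seed=seed,
                                        phase_range_rad=(0.0, 1.0)))
    pupil_phase = make_zernike_pupil_phase(
        sys_.objective_na, (h, h), orders=15, seed=seed + 1000,
        target_pv_rad=pv_rad, cutoff_radius_px=sys_.pupil_cutoff_px)
    obs, truth = simulate_fpm_dataset(amp, phs, sys_, pupil_phase, None)
    model = FpmModel(sys_, learn_pupil=True)
    cfg = SolverConfig(optimizer="adam", iterations=iterations, seed=seed,
                       learning_rates={"object": 0.05, "pupil": 0.05})
    res = solve(obs, model, FeatureExtractorSpec(kind="gradient"),
                LossSpec(), (), cfg)
    disk = sys_.ideal_pupil().support
    rms = pupil_phase_rms_error(res.params["pupil"], pupil_phase, disk)
    return {"pv_rad": pv_rad, "seed": seed, "pupil_rms_rad": rms,
            "object_psnr_db": _scaled_psnr(np.abs(res.object.values), amp)}


def _bench_system():
    k = led_grid_kvectors(9, 4000.0, 90000.0, 0.532)
    return FpmSystem(object_pixels=64, objective_na=0.25, wavelength_um=0.532,
                     camera_pitch_um=1.0, led_kvectors=k,
                     downsample_factor=2)


def vignette_comparison(seed: int = 0, iterations: int = 250) -> dict:
    """FD-PR vs pixel-domain least squares vs EPRY under half-plane
    vignetting plus noise; returns object-amplitude PSNRs."""
    sys_ = _bench_system()
    amp, phs = make_phantom(PhantomSpec(dims=(64, 64), seed=3,
                                        phase_range_rad=(0.0, 0.8)))
    degrade = DegradationSpec(vignette="half_plane", vignette_strength=1.0,
                              gaussian_sigma=0.01, poisson_photons=1e4,
                              seed=seed + 1)
    obs, truth = simulate_fpm_dataset(amp, phs, sys_, None, degrade)
    model = FpmModel(sys_, learn_pupil=True)
    cfg = SolverConfig(optimizer="adam", iterations=iterations, seed=seed,
                       learning_rates={"object": 0.05, "pupil": 0.01})
    fd = solve(obs, model, FeatureExtractorSpec(kind="gradient"),
               LossSpec(), (), cfg)
    px = solve(obs, model, FeatureExtractorSpec(kind="identity"),
               LossSpec(distance="l2"), (), cfg)
    ep = epry_fpm(obs, sys_, BaselineConfig(iterations=50))
    return {"fdpr_psnr_db": _scaled_psnr(np.abs(fd.object.values), amp),
            "pixel_clsr_psnr_db": _scaled_psnr(np.abs(px.object.values), amp),
            "epry_psnr_db": _scaled_psnr(np.abs(ep.object.values), amp)}


def aberration_comparison(seed: int = 0, pv_rad: float = 4 * np.pi,
                          iterations: int = 400) -> dict:
    """FD-PR vs EPRY vs mPIE on a heavily aberrated noisy FPM stack."""
    sys_ = _bench_system()
    amp, phs = make_phantom(PhantomSpec(dims=(64, 64), seed=3,
                                        phase_range_rad=(0.0, 0.8)))
    h = sys_.lowres_pixels
    pupil_phase = make_zernike_pupil_phase(
        sys_.objective_na, (h, h), orders=15, seed=seed + 2,
        target_pv_rad=pv_rad, cutoff_radius_px=sys_.pupil_cutoff_px)
    degrade = DegradationSpec(gaussian_sigma=0.01, poisson_photons=1e4,
                              seed=seed + 3)
    obs, truth = simulate_fpm_dataset(amp, phs, sys_, pupil_phase, degrade)
    model = FpmModel(sys_, learn_pupil=True)
    cfg = SolverConfig(optimizer="adam", iterations=iterations, seed=seed,
                       learning_rates={"object": 0.05, "pupil": 0.05})
    fd = solve(obs, model, FeatureExtractorSpec(kind="gradient"),
               LossSpec(), (), cfg)
    ep = epry_fpm(obs, sys_, BaselineConfig(iterations=50))
    mp = mpie_fpm(obs, sys_, BaselineConfig(iterations=50, momentum=0.3))
    return {"fdpr_psnr_db": _scaled_psnr(np.abs(fd.object.values), amp),
            "epry_psnr_db": _scaled_psnr(np.abs(ep.object.values), amp),
            "mpie_psnr_db": _scaled_psnr(np.abs(mp.object.values), amp)}


def holography_comparison(seed: int = 0, iterations: int = 700) -> dict:
    """Twin-image suppression on a wheel-like pure-phase phantom.

    Compares FD-PR with amplitude-clip + guided-filter constraints against
    unconstrained FD-PR and against Gerchberg-Saxton with a TV denoiser,
    on a noisy single-shot hologram.  Reports phase SSIM vs truth and final
    detector-amplitude L2 losses.
    """
    amp, phs = make_phantom(PhantomSpec(kind="wheel_phase", dims=(128, 128),
                                        seed=5, phase_range_rad=(0.0, 1.2)))
    obj = ComplexField(np.exp(1j * phs), 2.0, 0.532)
    degrade = DegradationSpec(gaussian_sigma=0.02, poisson_photons=1e4,
                              seed=seed + 9)
    obs, truth = simulate_inline_hologram(obj, 1500.0, degrade)
    amp_meas = np.sqrt(obs.frames[0])
    model = HolographyModel((128, 128), 2.0, 0.532, [1500.0])

    def detector_l2(params):
        u, _ = model.forward(params)
        return float(((np.abs(u[0]) - amp_meas) ** 2).sum())

    def phase_ssim(values):
        p = np.angle(values)
        p = p - np.median(p)
        return ssim(p, phs)

    cfg = SolverConfig(optimizer="yogi", iterations=iterations, seed=seed,
                       learning_rates={"object": 0.02})
    unconstrained = solve(obs, model, FeatureExtractorSpec(kind="gradient"),
                          LossSpec(), (), cfg)
    clip = ConstraintSpec(lambda x: C.amplitude_threshold(x, 0.0, 1.0),
                          weight=0.3, target="object",
                          name="amplitude_threshold")
    guided = ConstraintSpec(
        C.complex_constraint(lambda f: C.guided_filter(
            f, C.GuidedFilterParams(radius_px=8, eps=0.04)), "phase"),
        weight=1.0, target="object", name="guided_filter")
    constrained = solve(obs, model, FeatureExtractorSpec(kind="gradient"),
                        LossSpec(), (clip, guided), cfg)
    tv = C.complex_constraint(lambda f: C.tv_denoise(f, 0.05, 20), "phase")
    gs = gs_inline(obs.frames[0], 1500.0,
                   BaselineConfig(algorithm="gs", iterations=200),
                   constraints=[lambda x: C.amplitude_threshold(x, 0.0, 1.0),
                                tv],
                   wavelength_um=0.532, pixel_pitch_um=2.0)
    return {
        "ssim_guided": phase_ssim(constrained.object.values),
        "ssim_unconstrained": phase_ssim(unconstrained.object.values),
        "fdpr_detector_l2": detector_l2(constrained.params),
        "gs_detector_l2": float(gs.loss_trace[-1]),
    }
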