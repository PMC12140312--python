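import numpy as np
import pytest

from fdpr.core import FeatureExtractorSpec, LossSpec, SolverConfig
from fdpr.phantoms import PhantomSpec, make_phantom, simulate_fpm_dataset
from fdpr.propagators import FpmSystem, led_grid_kvectors


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_fpm_system(object_pixels=64, n_side=5, objective_na=0.25,
                    camera_pitch_um=1.0, downsample=2,
                    height_um=90000.0) -> FpmSystem:
    """Small FPM geometry used across the suite (32x32 low-res frames)."""
    k = led_grid_kvectors(n_side, 4000.0, height_um, 0.532)
    return FpmSystem(object_pixels=object_pixels, objective_na=objective_na,
                     wavelength_um=0.532, camera_pitch_um=camera_pitch_um,
                     led_kvectors=k, downsample_factor=downsample)


@pytest.fixture
def fpm_system():
    return make_fpm_system()


@pytest.fixture
def clean_fpm_dataset(fpm_system):
    amp, phs = make_phantom(PhantomSpec(dims=(64, 64), seed=3,
                                        phase_range_rad=(0.0, 0.8)))
    obs, truth = simulate_fpm_dataset(amp, phs, fpm_system, None, None)
    return obs, truth, fpm_system


@pytest.fixture
def gradient_spec():
    return FeatureExtractorSpec(kind="gradient")


@pytest.fixture
def charbonnier_loss():
    return LossSpec(distance="charbonnier")


def adam_config(iterations, seed=0, **rates):
    return SolverConfig(optimizer="adam", iterations=iterations, seed=seed,
                        learning_rates=rates)
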