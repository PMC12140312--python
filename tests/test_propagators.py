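import numpy as np
import pytest

from fdpr.core import (
    AngularSpectrumTransfer,
    ComplexField,
    ObservationSet,
    cfft2,
    cifft2,
    dot_product_test,
)
from fdpr.propagators import (
    CodedPtychographyModel,
    FpmModel,
    FpmSystem,
    HolographyModel,
    LenslessSystem,
    angular_spectrum_propagate,
    coded_ptych_forward,
    fpm_chain,
    fpm_forward,
    inline_holo_forward,
    led_grid_kvectors,
)

from conftest import make_fpm_system


def random_field(rng, n=64, pitch=0.5, wavelength=0.532):
    v = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    return ComplexField(v, pitch, wavelength)


class TestAngularSpectrum:
    def test_zero_distance_identity(self, rng):
        f = random_field(rng)
        out = angular_spectrum_propagate(f, 0.0)
        assert np.allclose(out.values, f.values, atol=1e-12)

    def test_round_trip(self, rng):
        f = random_field(rng)
        # restrict to the propagating band so the round trip is exact
        op = AngularSpectrumTransfer(f.shape, f.pixel_pitch_um,
                                     f.wavelength_um, 200.0)
        f.values = cifft2(cfft2(f.values) * op.band)
        back = angular_spectrum_propagate(
            angular_spectrum_propagate(f, 200.0), -200.0)
        assert np.abs(back.values - f.values).max() < 1e-10

    def test_energy_conservation(self, rng):
        f = random_field(rng)
        op = AngularSpectrumTransfer(f.shape, f.pixel_pitch_um,
                                     f.wavelength_um, 350.0)
        f.values = cifft2(cfft2(f.values) * op.band)
        out = angular_spectrum_propagate(f, 350.0)
        e0 = (np.abs(f.values) ** 2).sum()
        e1 = (np.abs(out.values) ** 2).sum()
        assert abs(e0 - e1) / e0 < 1e-10

    def test_gaussian_beam_width_law(self):
        """Propagated waist follows w(z) = w0 sqrt(1 + (z lambda/(pi w0^2))^2)."""
        lam, w0, z, n, pitch = 0.532, 10.0, 200.0, 256, 0.5
        yy, xx = (np.mgrid[:n, :n] - n / 2) * pitch
        f = ComplexField(np.exp(-(xx ** 2 + yy ** 2) / w0 ** 2), pitch, lam)
        intensity = np.abs(angular_spectrum_propagate(f, z).values) ** 2
        prof = intensity[n // 2]
        half = prof.max() / 2
        i1 = int(np.argmax(prof >= half))
        i2 = n - 1 - int(np.argmax(prof[::-1] >= half))
        x1 = i1 - 1 + (half - prof[i1 - 1]) / (prof[i1] - prof[i1 - 1])
        x2 = i2 + (half - prof[i2]) / (prof[i2 + 1] - prof[i2])
        fwhm = (x2 - x1) * pitch
        wz = w0 * np.sqrt(1 + (z * lam / (np.pi * w0 ** 2)) ** 2)
        expected = wz * np.sqrt(2 * np.log(2))  # FWHM of exp(-2 r^2/w^2)
        assert abs(fwhm - expected) / expected < 0.02

    def test_nonfinite_distance_rejected(self, rng):
        with pytest.raises(ValueError):
            angular_spectrum_propagate(random_field(rng), np.inf)


class TestFpmForward:
    def test_uniform_object_uniform_frame(self, fpm_system):
        obj = ComplexField(np.ones((64, 64), complex),
                           fpm_system.hires_pitch_um, 0.532)
        spec = ComplexField(cfft2(obj.values), fpm_system.hires_pitch_um,
                            0.532, plane="spectrum")
        frame = fpm_forward(spec, fpm_system.ideal_pupil(), fpm_system, 0)
        assert np.allclose(frame, frame.mean(), atol=1e-10)
        assert np.isclose(frame.mean(), 1.0)

    def test_tilt_outside_pupil_dark(self, fpm_system):
        # spatial frequency beyond the synthetic passband of frame 0
        n = 64
        cut = fpm_system.pupil_cutoff_px
        q = int(np.ceil(cut)) + 6
        yy, xx = np.mgrid[:n, :n]
        tilt = np.exp(2j * np.pi * q * xx / n)
        spec = ComplexField(cfft2(tilt), fpm_system.hires_pitch_um, 0.532,
                            plane="spectrum")
        frame = fpm_forward(spec, fpm_system.ideal_pupil(), fpm_system, 0)
        assert frame.sum() < 1e-12 * n * n

    def test_matches_direct_dft_oracle(self, fpm_system, rng):
        """Batch model frames equal a literal centered-DFT summation."""
        X = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        pupil = fpm_system.ideal_pupil()
        model = FpmModel(fpm_system, learn_pupil=False, pupil=pupil)
        frames = model.intensities({"object": X})
        h, H = 32, 64
        idx = np.arange(h) - h // 2
        E = np.exp(2j * np.pi * np.outer(idx, idx) / h) / np.sqrt(h)
        for n in [0, 7, 24]:
            sy, sx = fpm_system.shift_px(n)
            patch = X[H // 2 + sy - h // 2: H // 2 + sy + h // 2,
                      H // 2 + sx - h // 2: H // 2 + sx + h // 2]
            masked = patch * pupil.values * (h / H)
            u = E @ masked @ E.T
            ref = np.abs(u) ** 2
            assert np.abs(frames[n] - ref).max() < 1e-9 * ref.max()

    def test_chain_adjoint_every_led(self, fpm_system, rng):
        pupil = fpm_system.ideal_pupil()
        for n in range(0, fpm_system.n_leds, 5):
            chain = fpm_chain(fpm_system, pupil.values, n)
            assert dot_product_test(chain, (64, 64), (32, 32),
                                    rng) < 1e-10

    def test_lowpass_downsample_property(self, fpm_system, rng):
        """On-axis ideal-pupil FPM of a band-limited object is plain
        band-limited downsampling."""
        H, h = 64, 32
        spec = np.zeros((H, H), complex)
        inner = slice(H // 2 - 4, H // 2 + 4)  # well inside the pupil disk
        spec[inner, inner] = (rng.standard_normal((8, 8))
                              + 1j * rng.standard_normal((8, 8)))
        model = FpmModel(fpm_system, learn_pupil=False)
        frame0 = model.intensities({"object": spec})[0]
        low = cifft2(spec[H // 2 - h // 2: H // 2 + h // 2,
                          H // 2 - h // 2: H // 2 + h // 2] * (h / H))
        assert np.abs(frame0 - np.abs(low) ** 2).max() < 1e-9

    def test_pupil_mask_energy_monotone(self, fpm_system, rng):
        X = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        pupil = fpm_system.ideal_pupil()
        patch = X[16:48, 16:48]
        assert (np.abs(patch * pupil.values) ** 2).sum() <= \
            (np.abs(patch) ** 2).sum() + 1e-12

    def test_excessive_shift_rejected(self):
        sys_ = make_fpm_system(object_pixels=32, n_side=7,
                               height_um=30000.0, downsample=2,
                               objective_na=0.1)
        with pytest.raises(ValueError):
            fpm_chain(sys_, sys_.ideal_pupil().values, sys_.n_leds - 1)

    def test_synthetic_na_bound(self):
        with pytest.raises(ValueError):
            k = led_grid_kvectors(15, 20000.0, 20000.0, 0.532)
            FpmSystem(64, 0.6, 0.532, 1.0, k, 2)


class TestCodedForward:
    def _system(self, rng, n=64, d1=500.0, d2=1000.0, shifts=((0, 0), (5, -3))):
        pattern = ComplexField(
            np.exp(1j * np.pi * rng.integers(0, 2, (n, n))), 2.0, 0.532)
        return LenslessSystem(d1, d2, pattern, np.asarray(shifts))

    def test_degenerate_identity_chain(self, rng):
        obj = random_field(rng, pitch=2.0)
        sys_ = LenslessSystem(0.0, 0.0,
                              ComplexField(np.ones((64, 64)), 2.0, 0.532),
                              np.asarray([(0, 0), (1, 1)]))
        out = coded_ptych_forward(obj, sys_, 0)
        assert np.allclose(out, np.abs(obj.values) ** 2, atol=1e-10)

    def test_shift_equivariance_with_unit_pattern(self, rng):
        obj = random_field(rng, pitch=2.0)
        sys_ = LenslessSystem(500.0, 1000.0,
                              ComplexField(np.ones((64, 64)), 2.0, 0.532),
                              np.asarray([(0, 0), (7, -4)]))
        f0 = coded_ptych_forward(obj, sys_, 0)
        f1 = coded_ptych_forward(obj, sys_, 1)
        assert np.allclose(np.roll(f0, (7, -4), axis=(0, 1)), f1, atol=1e-10)

    def test_stage_composition_oracle(self, rng):
        obj = random_field(rng, pitch=2.0)
        sys_ = self._system(rng)
        out = coded_ptych_forward(obj, sys_, 1)
        shifted = ComplexField(np.roll(obj.values, (5, -3), axis=(0, 1)),
                               2.0, 0.532)
        step1 = angular_spectrum_propagate(shifted, 500.0)
        step2 = ComplexField(step1.values * sys_.coded_pattern.values,
                             2.0, 0.532)
        step3 = angular_spectrum_propagate(step2, 1000.0)
        assert np.abs(out - np.abs(step3.values) ** 2).max() < 1e-10

    def test_oversized_shift_rejected(self, rng):
        obj = random_field(rng, pitch=2.0)
        sys_ = self._system(rng, shifts=((0, 0), (40, 0)))
        with pytest.raises(ValueError):
            coded_ptych_forward(obj, sys_, 1)

    def test_model_matches_chain(self, rng):
        sys_ = self._system(rng)
        model = CodedPtychographyModel(sys_, (64, 64), 2.0, 0.532,
                                       learn_pattern=True)
        params = {"object": rng.standard_normal((64, 64)) + 0j,
                  "coded_pattern": sys_.coded_pattern.values.copy()}
        u, _ = model.forward(params)
        for n in range(2):
            ref = model.chain(params, n).apply(params["object"])
            assert np.abs(u[n] - ref).max() < 1e-12


class TestInlineHolography:
    def test_pure_phase_invisible_at_zero_distance(self, rng):
        phase = rng.uniform(-1, 1, (64, 64))
        obj = ComplexField(np.exp(1j * phase), 2.0, 0.532)
        holo = inline_holo_forward(obj, 0.0)
        assert np.allclose(holo, 1.0, atol=1e-12)

    def test_energy_conservation(self, rng):
        obj = random_field(rng, pitch=2.0)
        op = AngularSpectrumTransfer(obj.shape, 2.0, 0.532, 300.0)
        obj.values = cifft2(cfft2(obj.values) * op.band)
        holo = inline_holo_forward(obj, 300.0)
        assert abs(holo.sum() - (np.abs(obj.values) ** 2).sum()) \
            < 1e-10 * holo.sum()

    def test_phase_disk_fringes_match_two_stage_oracle(self):
        yy, xx = np.mgrid[:128, :128] - 64.0
        disk = 0.5 * (1 - np.tanh((np.hypot(yy, xx) - 8.0) / 1.5))
        obj = ComplexField(np.exp(0.5j * disk), 2.0, 0.532)
        holo = inline_holo_forward(obj, 300.0)
        ref = np.abs(angular_spectrum_propagate(obj, 300.0).values) ** 2
        assert np.array_equal(holo, ref)
        assert holo.std() > 1e-3  # concentric fringes are present

    def test_model_adjoint(self, rng):
        model = HolographyModel((32, 32), 2.0, 0.532, [300.0])
        chain = model.chain({}, 0)
        assert dot_product_test(chain, (32, 32), (32, 32), rng) < 1e-10
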