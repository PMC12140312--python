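import numpy as np
import pytest

from fdpr.core import (
    ComplexField,
    ConstraintSpec,
    FeatureExtractorSpec,
    LossSpec,
    ObservationSet,
    SolverConfig,
    cfft2,
)
from fdpr.engine import (
    OptState,
    apply_ehio_block,
    feature_loss,
    optimizer_step,
    solve,
    wirtinger_gradient,
)
from fdpr.features import extract
from fdpr.metrics import psnr, ssim
from fdpr.phantoms import (
    DegradationSpec,
    PhantomSpec,
    make_phantom,
    simulate_fpm_dataset,
    simulate_inline_hologram,
)
from fdpr.propagators import FpmModel, HolographyModel
from fdpr import constraints as C

from conftest import adam_config, make_fpm_system


def small_fpm_instance(rng, n=32, n_side=3):
    sys_ = make_fpm_system(object_pixels=n, n_side=n_side)
    model = FpmModel(sys_, learn_pupil=True)
    params = {"object": rng.standard_normal((n, n))
              + 1j * rng.standard_normal((n, n)),
              "pupil": sys_.ideal_pupil().values
              * np.exp(0.3j * rng.standard_normal((n // 2, n // 2)))}
    frames = model.intensities(params) * 0.8 + 0.05
    obs = ObservationSet(frames, list(map(tuple, sys_.led_kvectors)),
                         {"wavelength_um": 0.532, "pixel_pitch_um": 1.0})
    return model, params, obs


class TestFeatureLoss:
    def test_zero_at_equality(self, rng, gradient_spec):
        frames = rng.uniform(0, 1, (3, 16, 16))
        for dist in ("l1", "l2"):
            assert feature_loss(frames, frames, gradient_spec,
                                LossSpec(distance=dist)) == 0.0

    def test_l2_identity_direct_value(self):
        spec = FeatureExtractorSpec(kind="identity", scaling="identity")
        pred = np.ones((1, 2, 2))
        obs = np.zeros((1, 2, 2))
        assert feature_loss(pred, obs, spec, LossSpec(distance="l2")) == 4.0

    def test_matches_per_frame_direct_summation(self, rng, gradient_spec):
        """Batched loss equals a literal frame-by-frame, tensor-by-tensor sum."""
        loss = LossSpec(distance="charbonnier", charbonnier_epsilon=1e-3)
        pred = rng.uniform(0, 1, (4, 32, 32))
        obs = rng.uniform(0, 1, (4, 32, 32))
        value = feature_loss(pred, obs, gradient_spec, loss)
        eps = loss.charbonnier_epsilon
        ref = 0.0
        for n in range(4):
            tp = extract(pred[n], gradient_spec).tensors
            to = extract(obs[n], gradient_spec).tensors
            for a, b in zip(tp, to):
                r = a - b
                ref += float((np.sqrt(r * r + eps * eps) - eps).sum())
        assert abs(value - ref) < 1e-12 * max(ref, 1.0)

    def test_shape_mismatch_rejected(self, rng, gradient_spec):
        with pytest.raises(ValueError):
            feature_loss(rng.uniform(0, 1, (2, 8, 8)),
                         rng.uniform(0, 1, (2, 16, 16)),
                         gradient_spec, LossSpec())


class TestWirtingerGradient:
    def test_stationary_at_global_minimum(self, rng, gradient_spec):
        model, params, _ = small_fpm_instance(rng)
        frames = model.intensities(params)
        obs = ObservationSet(frames, [None] * len(frames),
                             {"wavelength_um": 0.532, "pixel_pitch_um": 1.0})
        grads, value = wirtinger_gradient(params, obs, model, gradient_spec,
                                          LossSpec(distance="l2"))
        assert value < 1e-16
        assert max(np.abs(g).max() for g in grads.values()) < 1e-8

    def test_single_pixel_analytic_form(self):
        """A = identity, D = l2, identity features: L = (|x|^2 - I)^2 has
        Wirtinger descent gradient 4 (|x|^2 - I) x."""

        class IdentityModel:
            targets = ["object"]

            def forward(self, params):
                return params["object"][None], {}

            def backprop(self, params, grad_fields, cache):
                return {"object": grad_fields[0]}

        x = np.array([[1.2 - 0.7j, 0.3 + 0.1j],
                      [-0.5 + 0.9j, 0.8 + 0.0j]])
        I = np.array([[0.5, 1.0], [0.2, 0.4]])
        spec = FeatureExtractorSpec(kind="identity", scaling="identity")
        obs = ObservationSet(I, [None], {})
        grads, value = wirtinger_gradient({"object": x}, obs,
                                          IdentityModel(), spec,
                                          LossSpec(distance="l2"))
        expected = 4.0 * (np.abs(x) ** 2 - I) * x
        assert np.allclose(grads["object"], expected, atol=1e-12)
        assert np.isclose(value, ((np.abs(x) ** 2 - I) ** 2).sum())

    @pytest.mark.parametrize("kind", ["gradient", "wavelet", "identity"])
    def test_matches_central_finite_differences(self, rng, kind):
        """dL/dRe(x) = Re(g), dL/dIm(x) = Im(g) on random coordinates of a
        seeded 32x32 joint object+pupil instance."""
        model, params, obs = small_fpm_instance(rng)
        spec = FeatureExtractorSpec(kind=kind, levels=3)
        loss = LossSpec(distance="charbonnier")
        grads, _ = wirtinger_gradient(params, obs, model, spec, loss)
        h = 1e-5
        for target, npix in (("object", 32), ("pupil", 16)):
            worst = 0.0
            coords = rng.integers(0, npix, size=(10, 2))
            if target == "pupil":
                # probe only active pupil pixels
                sup = np.argwhere(np.abs(params["pupil"]) > 0)
                coords = sup[rng.integers(0, len(sup), size=10)]
            for (i, j) in coords:
                for part, comp in ((1.0, np.real), (1j, np.imag)):
                    pp = {k: v.copy() for k, v in params.items()}
                    pp[target][i, j] += h * part
                    _, lp = wirtinger_gradient(pp, obs, model, spec, loss)
                    pp[target][i, j] -= 2 * h * part
                    _, lm = wirtinger_gradient(pp, obs, model, spec, loss)
                    fd = (lp - lm) / (2 * h)
                    an = comp(grads[target][i, j])
                    worst = max(worst, abs(fd - an)
                                / max(abs(fd), abs(an), 1e-10))
            assert worst < 1e-4, (kind, target, worst)

    def test_exact_l1_rejected_for_gradients(self, rng, gradient_spec):
        model, params, obs = small_fpm_instance(rng)
        with pytest.raises(ValueError):
            wirtinger_gradient(params, obs, model, gradient_spec,
                               LossSpec(distance="l1"))


class TestOptimizers:
    def test_zero_gradient_no_update(self):
        params = {"x": np.array([1.0 + 2.0j])}
        state = OptState(optimizer="adam")
        optimizer_step(state, params, {"x": np.zeros(1, complex)}, 0.1)
        assert params["x"][0] == 1.0 + 2.0j

    @pytest.mark.parametrize("opt", ["adam", "yogi"])
    def test_first_step_magnitude_is_lr(self, opt):
        params = {"x": np.array([0.0 + 0.0j])}
        state = OptState(optimizer=opt)
        g = np.array([0.3 - 0.4j])
        optimizer_step(state, params, {"x": g}, 0.05)
        assert np.isclose(np.abs(params["x"][0]), 0.05, rtol=1e-6)
        # step direction opposes the gradient
        assert np.isclose(np.angle(-params["x"][0]), np.angle(g[0]))

    def test_yogi_matches_hand_recursion(self):
        """Five scripted scalar gradients reproduce the additive
        second-moment recursion exactly."""
        gs = [0.5, -1.2, 0.8, 0.1, -0.4]
        b1, b2, eps, lr = 0.9, 0.999, 1e-8, 0.01
        m = v = 0.0
        x_ref = 0.0
        for t, g in enumerate(gs, start=1):
            m = b1 * m + (1 - b1) * g
            v = v - (1 - b2) * np.sign(v - g * g) * g * g
            x_ref -= lr * (m / (1 - b1 ** t)) \
                / (np.sqrt(v / (1 - b2 ** t)) + eps)
        params = {"x": np.array([0.0 + 0.0j])}
        state = OptState(optimizer="yogi", beta1=b1, beta2=b2, eps=eps)
        for g in gs:
            optimizer_step(state, params, {"x": np.array([g + 0.0j])}, lr)
        assert abs(params["x"][0].real - x_ref) < 1e-12

    def test_nan_gradient_rejected(self):
        state = OptState()
        with pytest.raises(FloatingPointError):
            optimizer_step(state, {"x": np.zeros(1, complex)},
                           {"x": np.array([np.nan + 0j])}, 0.1)


class TestEhioBlock:
    def test_zero_weight_disabled(self, rng):
        params = {"object": rng.standard_normal((8, 8)) + 0j}
        spec = ConstraintSpec(lambda x: np.zeros_like(x), weight=0.0)
        contrib, refined, penalty = apply_ehio_block(params, [spec])
        assert contrib == {} and penalty == 0.0

    def test_identity_constraint_no_contribution(self, rng):
        params = {"object": rng.standard_normal((8, 8)) + 0j}
        spec = ConstraintSpec(lambda x: x, weight=2.0)
        contrib, _, penalty = apply_ehio_block(params, [spec])
        assert np.allclose(contrib["object"], 0) and penalty == 0.0

    def test_support_mask_direct_evaluation(self):
        yy, xx = np.mgrid[:16, :16]
        disk = (yy - 8) ** 2 + (xx - 8) ** 2 <= 16
        params = {"object": np.ones((16, 16), complex)}
        spec = ConstraintSpec(C.support_projection(disk), weight=0.7)
        contrib, _, _ = apply_ehio_block(params, [spec])
        assert np.allclose(contrib["object"][disk], 0.0)
        assert np.allclose(contrib["object"][~disk], 2 * 0.7 * 1.0)

    def test_unknown_target_rejected(self):
        spec = ConstraintSpec(lambda x: x, weight=1.0, target="pupil")
        with pytest.raises(KeyError):
            apply_ehio_block({"object": np.zeros((2, 2))}, [spec])


class TestSolve:
    def test_zero_iterations_returns_init(self, clean_fpm_dataset,
                                          gradient_spec, charbonnier_loss):
        obs, truth, sys_ = clean_fpm_dataset
        model = FpmModel(sys_, learn_pupil=False)
        init = model.init_params(obs)
        res = solve(obs, model, gradient_spec, charbonnier_loss, (),
                    SolverConfig(iterations=0))
        assert len(res.loss_trace) == 0
        assert np.array_equal(res.params["object"], init["object"])

    def test_seed_determinism_bitwise(self, clean_fpm_dataset,
                                      gradient_spec, charbonnier_loss):
        obs, truth, sys_ = clean_fpm_dataset
        cfg = adam_config(8, object=0.05)
        traces = []
        for _ in range(2):
            model = FpmModel(sys_, learn_pupil=False)
            res = solve(obs, model, gradient_spec, charbonnier_loss, (), cfg)
            traces.append(res.loss_trace)
        assert np.array_equal(traces[0], traces[1])

    def test_sgd_descent_on_clean_data(self, clean_fpm_dataset,
                                       gradient_spec, charbonnier_loss):
        obs, truth, sys_ = clean_fpm_dataset
        model = FpmModel(sys_, learn_pupil=False)
        cfg = SolverConfig(optimizer="sgd", iterations=50,
                           learning_rates={"object": 1e-4})
        res = solve(obs, model, gradient_spec, charbonnier_loss, (), cfg)
        diffs = np.diff(res.loss_trace)
        assert np.all(diffs <= 1e-8 * np.abs(res.loss_trace[:-1]))

    def test_clean_fpm_deep_convergence(self, clean_fpm_dataset,
                                        gradient_spec):
        """Noiseless FPM regression drives the feature loss four orders of
        magnitude below its initial value."""
        obs, truth, sys_ = clean_fpm_dataset
        model = FpmModel(sys_, learn_pupil=False)
        cfg = adam_config(2000, object=0.02)
        res = solve(obs, model, gradient_spec, LossSpec(distance="l2"),
                    (), cfg)
        assert res.loss_trace.min() < 1e-4 * res.loss_trace[0]

    def test_phase_disk_hologram_recovery(self):
        """Single-shot recovery of a weak phase disk with eHIO constraints
        (unit amplitude each step, guided-filter cleanup at the end)."""
        yy, xx = np.mgrid[:128, :128] - 64.0
        phs = 0.25 * (1 - np.tanh((np.hypot(yy, xx) - 8.0) / 1.5))
        obj = ComplexField(np.exp(1j * phs), 2.0, 0.532)
        obs, _ = simulate_inline_hologram(obj, 1500.0, None)
        model = HolographyModel((128, 128), 2.0, 0.532, [1500.0])
        amp1 = ConstraintSpec(lambda x: C.amplitude_threshold(x, 1.0, 1.0),
                              1.0, "object", every=1)
        gf = ConstraintSpec(
            C.complex_constraint(lambda f: C.guided_filter(
                f, C.GuidedFilterParams(8, 0.01)), "phase"),
            1.0, "object", every=1500)
        cfg = SolverConfig(optimizer="adam", iterations=1500, seed=7,
                           learning_rates={"object": 0.02},
                           constraint_mode="hard")
        res = solve(obs, model, FeatureExtractorSpec(kind="gradient"),
                    LossSpec(), (amp1, gf), cfg)
        rec = np.angle(res.object.values)
        rec -= np.median(rec)
        assert ssim(rec, phs) > 0.9

    def test_feature_vs_pixel_vignette_robustness(self):
        """Under half-plane vignetting, gradient-feature solving beats the
        same engine run as pixel-domain least squares."""
        sys_ = make_fpm_system(n_side=9)
        amp, phs = make_phantom(PhantomSpec(dims=(64, 64), seed=3,
                                            phase_range_rad=(0.0, 0.8)))
        degrade = DegradationSpec(vignette="half_plane",
                                  vignette_strength=1.0,
                                  gaussian_sigma=0.01, seed=1)
        obs, truth = simulate_fpm_dataset(amp, phs, sys_, None, degrade)
        cfg = adam_config(250, object=0.05, pupil=0.01)
        model = FpmModel(sys_, learn_pupil=True)
        fd = solve(obs, model, FeatureExtractorSpec(kind="gradient"),
                   LossSpec(), (), cfg)
        px = solve(obs, model,
                   FeatureExtractorSpec(kind="identity"),
                   LossSpec(distance="l2"), (), cfg)
        p_fd = psnr(np.abs(fd.object.values), amp)
        p_px = psnr(np.abs(px.object.values), amp)
        assert p_fd > p_px
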