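"""The feature-domain phase-retrieval solver.

Phase retrieval is posed as a regression: the complex wavefront (and any
unknown operator parameters such as the pupil or the coded pattern) are
learned by gradient descent on the loss

    L = sum_n D( Theta(S(I_n_obs)), Theta(S(|A_n x|^2)) )
        + alpha ||x - C(x)||^2 + sum_k beta_k ||A_k - C(A_k)||^2

where ``Theta`` is a linear feature extractor, ``S`` a pointwise intensity
scaling, ``D`` a robust distance, and the ``C`` terms are plug-and-play
constraints applied through the extended-HIO block.  Gradients with respect
to the complex parameters are Wirtinger gradients (derivatives in the
conjugate coordinates), computed in closed form by pulling the loss gradient
back through ``D``, ``Theta``, ``S``, the intensity detection ``|.|^2`` and
the adjoint of the linear operator chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt

from .core import (
    ConstraintSpec,
    ComplexField,
    FeatureExtractorSpec,
    LossSpec,
    ObservationSet,
    SolverConfig,
)
from .features import (
    gradient_features,
    gradient_features_adjoint,
    scale_intensity,
    scale_intensity_derivative,
)

__all__ = [
    "OptState",
    "FitResult",
    "DivergenceError",
    "feature_loss",
    "wirtinger_gradient",
    "optimizer_step",
    "apply_ehio_block",
    "solve",
]


class DivergenceError(RuntimeError):
    """Raised when the loss explodes past 1e6 times its initial value."""


# ---------------------------------------------------------------------------
# batched feature extraction (internal; mirrors fdpr.features exactly)
# ---------------------------------------------------------------------------

def _engine_spec(spec: FeatureExtractorSpec,
                 frame_shape: tuple[int, int]) -> FeatureExtractorSpec:
    """Internal copy of the extractor spec usable on the solver's hot path.

    Wavelet features are evaluated in periodization mode (whose filter-bank
    transpose is the exact adjoint) and the level count is clamped to what
    the frame size supports.
    """
    if spec.kind != "wavelet":
        return spec
    max_lv = max(pywt.dwtn_max_level(frame_shape,
                                     pywt.Wavelet(spec.wavelet_name)), 1)
    return FeatureExtractorSpec(
        kind="wavelet", wavelet_name=spec.wavelet_name,
        levels=min(spec.levels, max_lv), scaling=spec.scaling,
        scaling_epsilon=spec.scaling_epsilon, wavelet_mode="periodization")


def _batched_features(frames: np.ndarray,
                      spec: FeatureExtractorSpec) -> list[np.ndarray]:
    scaled = scale_intensity(frames, spec)
    if spec.kind == "identity":
        return [scaled]
    if spec.kind == "gradient":
        return gradient_features(scaled).tensors
    coeffs = pywt.wavedec2(scaled, spec.wavelet_name, mode=spec.wavelet_mode,
                           level=spec.levels, axes=(-2, -1))
    tensors = [coeffs[0]]
    for band in coeffs[1:]:
        tensors.extend(band)
    return tensors


def _batched_feature_adjoint(frames: np.ndarray,
                             grad_tensors: Sequence[np.ndarray],
                             spec: FeatureExtractorSpec) -> np.ndarray:
    """S'(I) * Theta^T(g), vectorized over the frame axis."""
    if spec.kind == "identity":
        g = np.asarray(grad_tensors[0], dtype=float)
    elif spec.kind == "gradient":
        g = gradient_features_adjoint(list(grad_tensors))
    else:
        from .features import _adjoint_wavelet
        coeffs = [grad_tensors[0]]
        for i in range(1, len(grad_tensors), 3):
            coeffs.append(tuple(grad_tensors[i:i + 3]))
        adj = _adjoint_wavelet(spec.wavelet_name)
        g = pywt.waverec2(coeffs, adj, mode="periodization", axes=(-2, -1))
        g = g[..., : frames.shape[-2], : frames.shape[-1]]
    return g * scale_intensity_derivative(frames, spec)


def _tensor_weights(loss: LossSpec, n_tensors: int) -> np.ndarray:
    if loss.per_level_weights is None:
        return np.ones(n_tensors)
    w = np.asarray(loss.per_level_weights, dtype=float)
    if w.size == n_tensors:
        return w
    if n_tensors >= 4 and (n_tensors - 1) % 3 == 0 and w.size == (n_tensors - 1) // 3 + 1:
        # one weight for the approximation band + one per detail level
        out = [w[0]]
        for lv in range(1, w.size):
            out.extend([w[lv]] * 3)
        return np.asarray(out)
    raise ValueError(f"per_level_weights of size {w.size} does not match "
                     f"{n_tensors} feature tensors")


def _distance(r: np.ndarray, loss: LossSpec) -> float:
    if loss.distance == "l1":
        return float(np.abs(r).sum())
    if loss.distance == "l2":
        return float((r * r).sum())
    eps = loss.charbonnier_epsilon
    return float((np.sqrt(r * r + eps * eps) - eps).sum())


def _distance_grad(r: np.ndarray, loss: LossSpec) -> np.ndarray:
    if loss.distance == "l1":
        raise ValueError("exact l1 is not differentiable at 0; use the "
                         "charbonnier distance for gradient-based solving")
    if loss.distance == "l2":
        return 2.0 * r
    eps = loss.charbonnier_epsilon
    return r / np.sqrt(r * r + eps * eps)


# ---------------------------------------------------------------------------
# loss and Wirtinger gradient
# ---------------------------------------------------------------------------

def feature_loss(predicted_frames: np.ndarray, observed_frames: np.ndarray,
                 extractor: FeatureExtractorSpec, loss: LossSpec) -> float:
    """Feature-domain data misfit between predicted and observed intensities."""
    pred = np.asarray(predicted_frames, dtype=float)
    obs = np.asarray(observed_frames, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: predicted {pred.shape} vs "
                         f"observed {obs.shape}")
    spec = _engine_spec(extractor, pred.shape[-2:])
    t_pred = _batched_features(pred, spec)
    t_obs = _batched_features(obs, spec)
    w = _tensor_weights(loss, len(t_pred))
    return float(sum(wi * _distance(a - b, loss)
                     for wi, a, b in zip(w, t_pred, t_obs)))


def wirtinger_gradient(params: dict, observation: ObservationSet, model,
                       extractor: FeatureExtractorSpec, loss: LossSpec,
                       indices: np.ndarray | None = None):
    """Closed-form gradient of the feature-domain loss in conjugate coordinates.

    Returns ``(grads, loss_value)``.  The gradient convention is
    ``g = 2 * dL/d(conj(x))`` so that a real step ``t`` along ``-g`` changes
    the loss by ``-t * ||g||^2`` to first order; for the real and imaginary
    parts separately, ``dL/dRe(x) = Re(g)`` and ``dL/dIm(x) = Im(g)``.
    """
    fields, cache = model.forward(params)
    obs_frames = observation.frames
    if indices is not None:
        fields = fields[indices]
        obs_frames = obs_frames[indices]
    intens = np.abs(fields) ** 2
    spec = _engine_spec(extractor, intens.shape[-2:])
    t_pred = _batched_features(intens, spec)
    t_obs = _batched_features(obs_frames, spec)
    w = _tensor_weights(loss, len(t_pred))
    value = 0.0
    grad_tensors = []
    for wi, a, b in zip(w, t_pred, t_obs):
        r = a - b
        value += wi * _distance(r, loss)
        grad_tensors.append(wi * _distance_grad(r, loss))
    g_int = _batched_feature_adjoint(intens, grad_tensors, spec)
    grad_fields = 2.0 * g_int * fields
    if indices is not None:
        full = np.zeros((len(observation),) + grad_fields.shape[1:],
                        dtype=complex)
        full[indices] = grad_fields
        grad_fields = full
    grads = model.backprop(params, grad_fields, cache)
    for k, g in grads.items():
        if not np.all(np.isfinite(g.view(float))):
            raise FloatingPointError(f"non-finite gradient for {k!r}")
    return grads, float(value)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

@dataclass
class OptState:
    """Per-parameter first/second-moment accumulators for adaptive steps."""

    optimizer: str = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    step: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)


def optimizer_step(state: OptState, params: dict, grads: dict,
                   lr) -> tuple[dict, OptState]:
    """One in-place optimizer update of every parameter in ``params``.

    ``lr`` may be a float or a per-target mapping.  Complex parameters track
    second moments on the squared modulus of the complex gradient, so the
    adaptive scaling is phase-invariant.
    """
    state.step += 1
    t = state.step
    b1, b2, eps = state.beta1, state.beta2, state.eps
    for key, g in grads.items():
        if key not in params:
            continue
        if not np.all(np.isfinite(np.asarray(g).view(float))):
            raise FloatingPointError(f"NaN/inf gradient for parameter {key!r}")
        rate = lr[key] if isinstance(lr, dict) else float(lr)
        p = params[key]
        if state.optimizer == "sgd":
            params[key] = p - rate * g
            continue
        m = state.m.setdefault(key, np.zeros_like(g))
        if state.optimizer == "sgd_momentum":
            m *= b1
            m += g
            params[key] = p - rate * m
            continue
        v = state.v.setdefault(key, np.zeros_like(np.abs(g)))
        g2 = np.abs(g) ** 2
        m *= b1
        m += (1 - b1) * g
        if state.optimizer == "adam":
            v *= b2
            v += (1 - b2) * g2
        else:  # yogi: additive second-moment update
            v -= (1 - b2) * np.sign(v - g2) * g2
        m_hat = m / (1 - b1 ** t)
        v_hat = v / (1 - b2 ** t)
        params[key] = p - rate * m_hat / (np.sqrt(v_hat) + eps)
    return params, state


# ---------------------------------------------------------------------------
# eHIO constraint block
# ---------------------------------------------------------------------------

def apply_ehio_block(params: dict, constraints: Sequence[ConstraintSpec],
                     mode: str = "penalty", iteration: int | None = None,
                     default_every: int = 1):
    """Evaluate the plug-and-play constraint block.

    In ``penalty`` mode each constraint contributes ``2 * weight *
    (x - C(x))`` to its target's gradient, with ``C`` treated as fixed (no
    gradient flows through the refinement operator).  In ``hard`` mode the
    refined values ``C(x)`` are returned for direct replacement; a
    constraint fires on iterations divisible by its cadence (``every``,
    falling back to ``default_every``), or unconditionally when
    ``iteration`` is None.  Returns ``(gradient_contributions,
    refined_params, penalty_value)``.
    """
    contrib: dict = {}
    refined: dict = {}
    penalty = 0.0
    for spec in constraints:
        if spec.target not in params:
            raise KeyError(f"constraint target {spec.target!r} not among "
                           f"parameters {sorted(params)}")
        if mode == "hard" and iteration is not None:
            cadence = max(spec.every if spec.every is not None
                          else default_every, 1)
            if (iteration + 1) % cadence:
                continue
        x = refined.get(spec.target, params[spec.target])
        x_ref = spec.constraint(x)
        if mode == "hard":
            refined[spec.target] = x_ref
            continue
        diff = x - x_ref
        penalty += spec.weight * float(np.sum(np.abs(diff) ** spec.norm_order))
        if spec.weight > 0:
            c = contrib.setdefault(spec.target, np.zeros_like(x))
            c += 2.0 * spec.weight * diff
    return contrib, refined, penalty


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a solver run: best-loss iterate plus diagnostics."""

    object: ComplexField
    params: dict
    loss_trace: np.ndarray
    config: SolverConfig
    seed: int
    constraint_mode: str = "penalty"
    best_iteration: int = -1

    def __post_init__(self):
        self.loss_trace = np.asarray(self.loss_trace, dtype=float)
        if not np.all(np.isfinite(self.loss_trace)):
            raise ValueError("loss trace contains non-finite values")


def solve(observation: ObservationSet, model,
          extractor: FeatureExtractorSpec | None = None,
          loss: LossSpec | None = None,
          constraints: Sequence[ConstraintSpec] = (),
          config: SolverConfig | None = None,
          init: dict | None = None) -> FitResult:
    """Run feature-domain phase retrieval and return the best-loss iterate.

    Each iteration computes the Wirtinger gradient of the feature-domain
    likelihood, adds the eHIO penalty contributions, and applies one
    optimizer step per parameter group; the model's physical projection
    (pupil support, amplitude clamp) runs after every step.  Deterministic
    for a fixed config and seed.
    """
    extractor = extractor or FeatureExtractorSpec()
    loss = loss or LossSpec()
    config = config or SolverConfig()
    params = dict(init) if init is not None else model.init_params(observation)
    params = {k: np.array(v, dtype=complex) for k, v in params.items()}

    state = OptState(optimizer=config.optimizer, beta1=config.beta1,
                     beta2=config.beta2, eps=config.eps)
    lr = {k: config.lr(k) for k in params}
    rng = np.random.default_rng(config.seed)
    n_frames = len(observation)

    trace = []
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_it = -1
    initial = None
    for it in range(config.iterations):
        indices = None
        if 0 < config.batch_size < n_frames:
            indices = rng.choice(n_frames, size=config.batch_size,
                                 replace=False)
        grads, data_loss = wirtinger_gradient(params, observation, model,
                                              extractor, loss, indices=indices)
        penalty = 0.0
        if config.constraint_mode == "penalty":
            contrib, _, penalty = apply_ehio_block(params, constraints,
                                                   mode="penalty")
            for k, g in contrib.items():
                grads[k] = grads.get(k, 0) + g
        total = data_loss + penalty
        if initial is None:
            initial = total
        # the +1 floor keeps a near-perfect initialization (loss ~ 0) from
        # flagging ordinary constraint-driven loss increases as divergence
        if total > 1e6 * (initial + 1.0):
            raise DivergenceError(
                f"loss {total:.3e} exceeded 1e6 x initial {initial:.3e} at "
                f"iteration {it}; reduce the learning rates")
        if total < best_loss:
            best_loss = total
            best_params = {k: v.copy() for k, v in params.items()}
            best_it = it
        optimizer_step(state, params, grads, lr)
        if config.constraint_mode == "hard" and constraints:
            _, refined, _ = apply_ehio_block(params, constraints, "hard",
                                             iteration=it,
                                             default_every=config.hard_every)
            for k, v in refined.items():
                params[k] = np.asarray(v, dtype=complex)
        model.project(params)
        trace.append(total)
        if config.log_every and (it + 1) % config.log_every == 0:
            print(f"[fdpr] iter {it + 1:5d}  loss {total:.6e}")
        if config.stop_tol > 0 and len(trace) > 1:
            prev = trace[-2]
            if prev > 0 and abs(prev - total) / prev < config.stop_tol:
                break

    if config.constraint_mode == "hard":
        # hard replacement deliberately trades data consistency for
        # feasibility, so the final (refined) iterate is the answer
        best_params = params
        best_it = config.iterations - 1
    elif config.iterations > 0:
        # evaluate the final iterate too: it may beat every pre-step loss
        final_frames = model.intensities(params)
        final_loss = feature_loss(final_frames, observation.frames,
                                  extractor, loss)
        final_loss += apply_ehio_block(params, constraints, "penalty")[2]
        if final_loss < best_loss:
            best_loss = final_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_it = config.iterations

    return FitResult(object=model.object_field(best_params),
                     params=best_params, loss_trace=np.asarray(trace),
                     config=config, seed=config.seed,
                     constraint_mode=config.constraint_mode,
                     best_iteration=best_it)


def yogi_config(iterations: int = 500, seed: int = 0, **rates) -> SolverConfig:
    """Convenience: a YOGI-accelerated solver configuration."""
    return SolverConfig(optimizer="yogi", iterations=iterations, seed=seed,
                        learning_rates=rates)
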