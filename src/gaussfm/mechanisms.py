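"""Private fitting procedures on pooled data.

All four mechanisms share the same pipeline: decompose the cost into its
quadratic coefficients (beta, alpha, M), perturb the coefficients, repair
positive semi-definiteness, and minimize the noisy quadratic in closed form.
They differ only in how the noise is calibrated:

* :func:`gaussian_fm_fit` -- Gaussian noise calibrated per coefficient order
  with the dimension-free sensitivities (Delta_0, Delta_1, Delta_2);
* :func:`laplace_fm_fit` -- the classic functional mechanism: i.i.d. Laplace
  noise with the single scheme-wide L1 sensitivity (pure eps-DP);
* :func:`relaxed_fm_fit` -- Gaussian noise with the single scheme-wide L2
  sensitivity (the relaxed functional mechanism);
* :func:`noisy_gd_fit` -- the gradient-perturbation baseline: clipped
  per-sample gradients of the *exact* cost plus per-iteration Gaussian
  noise, with the overall privacy loss tracked by RDP composition.

Budgets are expressed either as (epsilon, delta) or directly as a
per-unit-sensitivity noise multiplier sigma (the experiments' x-axis); a
mechanism's actual noise sd is its sensitivity times sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import accounting, sensitivity
from .data import LabeledDataset, as_rng
from .objective import (
    LINEAR,
    LOGISTIC,
    QuadraticObjective,
    decompose,
    minimize,
    repair_psd,
    sigmoid,
    symmetric_gaussian_matrix,
    truncate_spectrum,
    wigner_edge,
)

__all__ = [
    "PrivacyBudget",
    "FitResult",
    "nonprivate_fit",
    "gaussian_fm_fit",
    "laplace_fm_fit",
    "relaxed_fm_fit",
    "noisy_gd_fit",
]


@dataclass(frozen=True)
class PrivacyBudget:
    """Either an (epsilon, delta) pair or a raw noise multiplier sigma.

    Exactly one parameterization must be active.  ``multiplier()`` returns
    sigma = tau/Delta, the Gaussian noise sd per unit of L2 sensitivity; with
    (epsilon, delta) this is sqrt(2 ln(1.25/delta)) / epsilon.
    """

    epsilon: float | None = None
    delta: float | None = None
    noise_multiplier: float | None = None

    def __post_init__(self) -> None:
        eps_mode = self.epsilon is not None or self.delta is not None
        sigma_mode = self.noise_multiplier is not None
        if eps_mode == sigma_mode:
            raise ValueError(
                "specify exactly one of (epsilon, delta) or noise_multiplier"
            )
        if eps_mode:
            if self.epsilon is None or self.delta is None:
                raise ValueError("epsilon and delta must be given together")
            if self.epsilon <= 0:
                raise ValueError("epsilon must be positive")
            if not 0.0 < self.delta < 1.0:
                raise ValueError("delta must be in (0, 1)")
        elif self.noise_multiplier < 0:
            raise ValueError("noise_multiplier must be non-negative")

    def multiplier(self) -> float:
        if self.noise_multiplier is not None:
            return self.noise_multiplier
        return accounting.gaussian_noise_multiplier(self.epsilon, self.delta)

    def implied_epsilon(self, delta: float = 1e-5) -> float:
        """The single-shot epsilon this budget corresponds to at the given delta."""
        if self.epsilon is not None:
            return self.epsilon
        return accounting.gaussian_epsilon_from_multiplier(
            self.noise_multiplier, delta
        )


@dataclass
class FitResult:
    """A private (or reference) model fit with its mechanism metadata."""

    weights: np.ndarray
    mechanism: str
    seed: int | None = None
    noise_levels: dict[str, float] = field(default_factory=dict)
    psd_repair_applied: bool = False
    overall_epsilon: float | None = None
    #: the noisy quadratic objective before PSD repair (None for noisy-gd);
    #: lets callers audit the injected coefficient noise directly
    objective: "QuadraticObjective | None" = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("fitted weights must be finite")

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.weights


def _model_for(ds: LabeledDataset, model: str | None) -> str:
    inferred = LINEAR if ds.task == "regression" else LOGISTIC
    if model is not None and model != inferred:
        raise ValueError(f"model {model!r} does not match dataset task {ds.task!r}")
    return inferred


def _finish(
    obj: QuadraticObjective, mechanism: str, seed, noise, eps, m_noise_sd: float = 0.0
) -> FitResult:
    # repair PSD, then drop eigenvalues below the quadratic part's noise edge:
    # curvature below that level is pure noise and inverting it is unstable
    repaired = repair_psd(obj)
    stabilized = truncate_spectrum(repaired, wigner_edge(obj.dim, m_noise_sd))
    w = minimize(stabilized)
    return FitResult(
        weights=w,
        mechanism=mechanism,
        seed=seed if isinstance(seed, int) else None,
        noise_levels=noise,
        psd_repair_applied=repaired.psd_clipped,
        overall_epsilon=eps,
        objective=obj,
    )


def nonprivate_fit(ds: LabeledDataset, model: str | None = None) -> FitResult:
    """Noise-free minimizer of the (surrogate) quadratic objective."""
    _model_for(ds, model)
    obj = decompose(ds)
    return _finish(obj, "non-priv", None, {}, None)


def gaussian_fm_fit(
    ds: LabeledDataset,
    budget: PrivacyBudget,
    seed: int | np.random.Generator | None = None,
    model: str | None = None,
) -> FitResult:
    """Gaussian functional mechanism with per-order noise calibration.

    Each coefficient order j gets Gaussian noise with sd tau_j = Delta_j *
    sigma: a scalar on beta, an i.i.d. vector on alpha, and an exactly
    symmetric matrix (upper triangle drawn, mirrored) on M.  With sigma = 0
    the non-private minimizer is returned exactly.

    After PSD repair, eigenvalues of the noisy M below its noise edge
    (2 tau_2 sqrt(D)) are dropped before the pseudoinverse solve: because
    the per-order calibration keeps tau_2 small, the informative curvature
    sits above that edge, and inverting sub-edge eigenvalues -- noise that
    the eigenvalue projection happened to leave slightly positive --
    amplifies the solution without bound.  The truncation is deterministic
    post-processing and vanishes when sigma = 0.
    """
    mdl = _model_for(ds, model)
    rng = as_rng(seed)
    sigma = budget.multiplier()
    d0, d1, d2 = sensitivity.gauss_fm_sensitivities(mdl, ds.n_samples)
    t0, t1, t2 = d0 * sigma, d1 * sigma, d2 * sigma
    obj = decompose(ds)
    noisy = QuadraticObjective(
        obj.constant + (rng.normal(0.0, t0) if t0 > 0 else 0.0),
        obj.linear + (rng.normal(0.0, t1, size=obj.dim) if t1 > 0 else 0.0),
        obj.quadratic
        + (symmetric_gaussian_matrix(obj.dim, t2, rng) if t2 > 0 else 0.0),
        mdl,
    )
    return _finish(
        noisy,
        "gauss-fm",
        seed,
        {"tau0": t0, "tau1": t1, "tau2": t2},
        budget.epsilon,
        m_noise_sd=t2,
    )


def laplace_fm_fit(
    ds: LabeledDataset,
    epsilon: float | None = None,
    seed: int | np.random.Generator | None = None,
    model: str | None = None,
    noise_multiplier: float | None = None,
) -> FitResult:
    """Classic functional mechanism: i.i.d. Laplace(scale = Delta_fm / eps).

    Every entry of beta, alpha and the full M matrix is perturbed with the
    single scheme-wide L1 sensitivity; M is then symmetrized.  When driven by
    a noise multiplier sigma instead of epsilon, the scale is chosen so the
    per-entry noise sd equals Delta_fm * sigma (sd of Laplace(b) is b*sqrt 2).
    """
    mdl = _model_for(ds, model)
    if (epsilon is None) == (noise_multiplier is None):
        raise ValueError("specify exactly one of epsilon or noise_multiplier")
    rng = as_rng(seed)
    delta_fm = sensitivity.fm_l1_sensitivity(mdl, ds.n_samples, ds.n_features)
    if epsilon is not None:
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        scale = 0.0 if math.isinf(epsilon) else delta_fm / epsilon
    else:
        scale = delta_fm * noise_multiplier / math.sqrt(2.0)
    obj = decompose(ds)
    if scale > 0:
        e2 = rng.laplace(0.0, scale, size=(obj.dim, obj.dim))
        noisy = QuadraticObjective(
            obj.constant + rng.laplace(0.0, scale),
            obj.linear + rng.laplace(0.0, scale, size=obj.dim),
            obj.quadratic + 0.5 * (e2 + e2.T),
            mdl,
        )
    else:
        noisy = obj
    # baseline reproduced as published: PSD repair + pseudoinverse, no
    # spectral stabilization (see gaussian_fm_fit)
    return _finish(noisy, "fm", seed, {"laplace_scale": scale}, epsilon)


def relaxed_fm_fit(
    ds: LabeledDataset,
    budget: PrivacyBudget,
    seed: int | np.random.Generator | None = None,
    model: str | None = None,
) -> FitResult:
    """Relaxed functional mechanism: one Gaussian noise level for all orders.

    tau = Delta_rlx * sigma is applied i.i.d. to every coefficient; the M
    noise is symmetrized before PSD repair.
    """
    mdl = _model_for(ds, model)
    rng = as_rng(seed)
    delta_rlx = sensitivity.rlx_fm_l2_sensitivity(mdl, ds.n_samples, ds.n_features)
    tau = delta_rlx * budget.multiplier()
    obj = decompose(ds)
    if tau > 0:
        e2 = rng.normal(0.0, tau, size=(obj.dim, obj.dim))
        noisy = QuadraticObjective(
            obj.constant + rng.normal(0.0, tau),
            obj.linear + rng.normal(0.0, tau, size=obj.dim),
            obj.quadratic + 0.5 * (e2 + e2.T),
            mdl,
        )
    else:
        noisy = obj
    # baseline reproduced as published: PSD repair + pseudoinverse, no
    # spectral stabilization (see gaussian_fm_fit)
    return _finish(noisy, "rlx-fm", seed, {"tau": tau}, budget.epsilon)


def _per_sample_gradients(
    ds: LabeledDataset, model: str, w: np.ndarray
) -> np.ndarray:
    x, y = ds.features, ds.labels
    if model == LINEAR:
        residual = x @ w - y
        return 2.0 * residual[:, None] * x
    return (sigmoid(x @ w) - y)[:, None] * x


def noisy_gd_fit(
    ds: LabeledDataset,
    t_iters: int = 100,
    clip: float = 1.0,
    step: float = 0.5,
    epsilon_iter: float | None = 0.5,
    delta_iter: float = 1e-5,
    seed: int | np.random.Generator | None = None,
    model: str | None = None,
    noise_multiplier: float | None = None,
) -> FitResult:
    """Gradient perturbation on the exact (unapproximated) cost.

    Per iteration: per-sample gradients are clipped to L2 norm <= ``clip``,
    averaged (replace-one L2 sensitivity 2*clip/N), and Gaussian noise with
    sd = (2*clip/N) * sigma is added per coordinate before a fixed-step
    update.  The overall privacy loss is the RDP composition of the T
    iterations at delta_r = ``delta_iter``.
    """
    mdl = _model_for(ds, model)
    if t_iters < 1:
        raise ValueError("t_iters must be >= 1")
    if clip <= 0 or step <= 0:
        raise ValueError("clip and step must be positive")
    if (epsilon_iter is None) == (noise_multiplier is None):
        raise ValueError("specify exactly one of epsilon_iter or noise_multiplier")
    rng = as_rng(seed)
    sigma = (
        noise_multiplier
        if noise_multiplier is not None
        else accounting.gaussian_noise_multiplier(epsilon_iter, delta_iter)
    )
    grad_sens = 2.0 * clip / ds.n_samples
    noise_sd = grad_sens * sigma

    w = np.zeros(ds.n_features)
    for it in range(t_iters):
        grads = _per_sample_gradients(ds, mdl, w)
        norms = np.linalg.norm(grads, axis=1)
        factors = np.minimum(1.0, clip / np.maximum(norms, 1e-300))
        g = (grads * factors[:, None]).mean(axis=0)
        if noise_sd > 0:
            g = g + rng.normal(0.0, noise_sd, size=ds.n_features)
        w = w - step * g
        if not np.isfinite(w).all():
            raise FloatingPointError(
                f"noisy gradient descent diverged at iteration {it + 1}"
            )
    overall = (
        accounting.rdp_overall_epsilon(t_iters, sigma, delta_iter).epsilon_opt
        if sigma > 0
        else math.inf
    )
    return FitResult(
        weights=w,
        mechanism="noisy-gd",
        seed=seed if isinstance(seed, int) else None,
        noise_levels={"grad_noise_sd": noise_sd, "sigma": sigma},
        psd_repair_applied=False,
        overall_epsilon=overall,
    )
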