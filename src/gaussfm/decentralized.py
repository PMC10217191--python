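"""Decentralized functional mechanism with correlated (CAPE) noise.

S sites each hold a disjoint shard of the data.  In the conventional scheme
every site releases its local quadratic coefficients with full local noise
(sd tau_js calibrated to the local sensitivity Delta_j(N_s)), and averaging S
such releases leaves an aggregated noise variance of tau_js^2 / S -- a factor
S worse than if the data were pooled.

CAPE removes that penalty: each site's release carries a *correlated*
zero-sum term e_s (variances (1 - 1/S) tau_js^2, sum over sites exactly
zero) plus a small independent local term g_s (variance tau_js^2 / S).  Each
individual release is as noisy as before, so per-site privacy is preserved,
but the correlated terms cancel in the aggregator's average and only the
small local terms survive: aggregated variance tau_js^2 / S^2, matching the
pooled-data scenario in the symmetric setting.

The secure-aggregation step that lets sites compute the zero-sum term
without revealing their raw draws is simulated functionally: the draws are
centered in the clear here, with the contract that only their sum would ever
leave the sites in a real deployment.  The privacy statements depend only on
the noise statistics, which are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sensitivity
from .data import SiteCollection, as_rng
from .mechanisms import FitResult, PrivacyBudget, _finish, _model_for
from .objective import QuadraticObjective, decompose, symmetric_gaussian_matrix

__all__ = [
    "NoiseShares",
    "zero_sum_noise",
    "cape_fm_fit",
    "conventional_decentralized_fit",
]


@dataclass
class NoiseShares:
    """Per-site correlated noise for one coefficient order.

    ``raw`` holds the sites' independent draws e_hat_s ~ N(0, tau_s^2);
    ``correlated`` the centered shares e_s = e_hat_s - mean_s'(e_hat_s'),
    which sum to zero exactly (up to float cancellation) across sites.
    """

    raw: np.ndarray  # shape (S, *coef_shape)
    correlated: np.ndarray  # shape (S, *coef_shape)
    tau_s: float

    @property
    def n_sites(self) -> int:
        return self.raw.shape[0]

    def site_sum(self) -> np.ndarray:
        return self.correlated.sum(axis=0)


def zero_sum_noise(
    n_sites: int,
    tau_s: float,
    shape: tuple[int, ...],
    rng: int | np.random.Generator | None = None,
    symmetric: bool = False,
) -> NoiseShares:
    """Draw per-site zero-sum Gaussian noise shares for one coefficient array.

    Each site draws e_hat_s with i.i.d. N(0, tau_s^2) entries (an exactly
    symmetric matrix draw when ``symmetric`` is set, as needed for the
    order-2 coefficient), and the shares are centered across sites.  The
    centered shares have per-entry variance (1 - 1/S) tau_s^2.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if tau_s < 0:
        raise ValueError("tau_s must be non-negative")
    rng = as_rng(rng)
    if symmetric:
        if len(shape) != 2 or shape[0] != shape[1]:
            raise ValueError("symmetric noise requires a square shape")
        raw = np.stack(
            [symmetric_gaussian_matrix(shape[0], tau_s, rng) for _ in range(n_sites)]
        )
    else:
        raw = rng.normal(0.0, tau_s, size=(n_sites, *shape))
    correlated = raw - raw.mean(axis=0, keepdims=True)
    return NoiseShares(raw=raw, correlated=correlated, tau_s=tau_s)


def _site_taus(sites: SiteCollection, model: str, sigma: float) -> list[tuple[float, ...]]:
    """Per-site per-order noise sds tau_js = Delta_j(N_s) * sigma."""
    return [
        tuple(d * sigma for d in sensitivity.gauss_fm_sensitivities(model, ns))
        for ns in sites.site_sizes
    ]


def _check_sites(sites: SiteCollection) -> None:
    if len(set(sites.site_sizes)) != 1:
        raise ValueError("decentralized fits require the symmetric setting")


def cape_fm_fit(
    sites: SiteCollection,
    budget: PrivacyBudget,
    seed: int | np.random.Generator | None = None,
    model: str | None = None,
) -> FitResult:
    """Decentralized Gaussian functional mechanism with CAPE noise.

    Per site s and order j: local coefficients Lambda_js from the site's own
    decomposition; a correlated zero-sum share e_js (site-level sd tau_js,
    symmetric matrices for j = 2); an independent local share g_js with sd
    tau_js / sqrt(S).  The aggregator averages the perturbed coefficients --
    the zero-sum terms cancel exactly -- then repairs PSD once and minimizes.
    """
    _check_sites(sites)
    pooled = sites.pooled()
    mdl = _model_for(pooled, model)
    rng = as_rng(seed)
    sigma = budget.multiplier()
    s = sites.n_sites
    d = sites.n_features
    taus = _site_taus(sites, mdl, sigma)
    # symmetric setting: all sites share tau_js
    t0, t1, t2 = taus[0]

    locals_ = [decompose(site) for site in sites.sites]

    e0 = zero_sum_noise(s, t0, (), rng)
    e1 = zero_sum_noise(s, t1, (d,), rng)
    e2 = zero_sum_noise(s, t2, (d, d), rng, symmetric=True)

    sqrt_s = np.sqrt(s)
    g0 = rng.normal(0.0, t0 / sqrt_s, size=s) if t0 > 0 else np.zeros(s)
    g1 = rng.normal(0.0, t1 / sqrt_s, size=(s, d)) if t1 > 0 else np.zeros((s, d))
    g2 = (
        np.stack([symmetric_gaussian_matrix(d, t2 / sqrt_s, rng) for _ in range(s)])
        if t2 > 0
        else np.zeros((s, d, d))
    )

    beta = np.mean(np.array([o.constant for o in locals_]) + e0.correlated + g0)
    alpha = np.mean(
        np.stack([o.linear for o in locals_]) + e1.correlated + g1, axis=0
    )
    quad = np.mean(
        np.stack([o.quadratic for o in locals_]) + e2.correlated + g2, axis=0
    )
    quad = 0.5 * (quad + quad.T)
    noisy = QuadraticObjective(float(beta), alpha, quad, mdl)
    return _finish(
        noisy,
        "cape-fm",
        seed,
        {"tau0_site": t0, "tau1_site": t1, "tau2_site": t2, "sites": float(s)},
        budget.epsilon,
        m_noise_sd=t2 / s,  # aggregated local-noise sd: (t2/sqrt(S))/sqrt(S)
    )


def conventional_decentralized_fit(
    sites: SiteCollection,
    budget: PrivacyBudget,
    seed: int | np.random.Generator | None = None,
    model: str | None = None,
) -> FitResult:
    """Conventional decentralized baseline: full local noise at every site.

    Each site perturbs its local coefficients with the complete locally
    calibrated Gaussian noise (sd tau_js); the aggregator averages, repairs
    and minimizes.  Aggregated noise variance is tau_js^2 / S.
    """
    _check_sites(sites)
    pooled = sites.pooled()
    mdl = _model_for(pooled, model)
    rng = as_rng(seed)
    sigma = budget.multiplier()
    s = sites.n_sites
    d = sites.n_features
    t0, t1, t2 = _site_taus(sites, mdl, sigma)[0]

    locals_ = [decompose(site) for site in sites.sites]
    beta = np.mean(
        [o.constant + (rng.normal(0.0, t0) if t0 > 0 else 0.0) for o in locals_]
    )
    alpha = np.mean(
        np.stack(
            [
                o.linear + (rng.normal(0.0, t1, size=d) if t1 > 0 else 0.0)
                for o in locals_
            ]
        ),
        axis=0,
    )
    quad = np.mean(
        np.stack(
            [
                o.quadratic
                + (symmetric_gaussian_matrix(d, t2, rng) if t2 > 0 else 0.0)
                for o in locals_
            ]
        ),
        axis=0,
    )
    quad = 0.5 * (quad + quad.T)
    noisy = QuadraticObjective(float(beta), alpha, quad, mdl)
    return _finish(
        noisy,
        "conventional",
        seed,
        {"tau0_site": t0, "tau1_site": t1, "tau2_site": t2, "sites": float(s)},
        budget.epsilon,
        m_noise_sd=t2 / np.sqrt(s),  # mean of S independent site draws
    )
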