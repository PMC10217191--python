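"""Privacy bookkeeping.

Three kinds of accounting live here:

* the Gaussian mechanism's calibration tau = (Delta/eps) sqrt(2 ln(1.25/delta))
  and its inversion (recovering the epsilon implied by a noise multiplier);
* Renyi-DP composition for iterative mechanisms: a T-fold composition of
  Gaussian mechanisms with per-unit-sensitivity noise sigma satisfies
  (alpha, alpha T / (2 sigma^2))-RDP, which converts to (eps, delta_r)-DP.
  Optimizing the conversion over alpha gives

      alpha_opt = 1 + sqrt(2 sigma^2 ln(1/delta_r) / T),
      eps_opt   = alpha_opt T / (2 sigma^2) + ln(1/delta_r) / (alpha_opt - 1);

* the CAPE correlated-noise protocol's collusion/variance accounting
  (colluder threshold, per-site noise split, pooled-equivalence ratios).

Natural logarithms throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "RdpAccount",
    "CapeAccount",
    "calibrate_gaussian",
    "gaussian_epsilon_from_multiplier",
    "rdp_overall_epsilon",
    "collusion_threshold",
    "cape_delta",
    "cape_noise_split",
    "cape_gain",
    "cape_H",
]


def calibrate_gaussian(sensitivity: float, epsilon: float, delta: float) -> float:
    """Noise sd for the Gaussian mechanism: (Delta/eps) sqrt(2 ln(1.25/delta)).

    The classical guarantee is stated for eps in (0, 1); larger values are
    accepted with a warning (common practice, weaker theory).
    """
    if sensitivity < 0:
        raise ValueError("sensitivity must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    if epsilon >= 1.0:
        warnings.warn(
            "Gaussian-mechanism calibration is stated for epsilon < 1; "
            f"got epsilon={epsilon:g}",
            UserWarning,
            stacklevel=2,
        )
    return (sensitivity / epsilon) * math.sqrt(2.0 * math.log(1.25 / delta))


def gaussian_noise_multiplier(epsilon: float, delta: float) -> float:
    """Per-unit-sensitivity noise multiplier sigma = tau / Delta."""
    return calibrate_gaussian(1.0, epsilon, delta)


def gaussian_epsilon_from_multiplier(sigma: float, delta: float) -> float:
    """Invert the calibration: the epsilon implied by multiplier sigma at delta."""
    if sigma <= 0:
        return math.inf if sigma == 0 else float("nan")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    return math.sqrt(2.0 * math.log(1.25 / delta)) / sigma


@dataclass(frozen=True)
class RdpAccount:
    """Result of RDP composition for T Gaussian mechanisms."""

    t: int
    noise_to_sensitivity: float
    delta_r: float
    alpha_opt: float
    epsilon_opt: float

    def epsilon_at(self, alpha: float) -> float:
        """(eps, delta_r) conversion at an arbitrary Renyi order alpha > 1."""
        if alpha <= 1:
            raise ValueError("alpha must be > 1")
        sigma2 = self.noise_to_sensitivity**2
        return alpha * self.t / (2.0 * sigma2) + math.log(1.0 / self.delta_r) / (
            alpha - 1.0
        )


def rdp_overall_epsilon(
    t: int, noise_to_sensitivity: float, delta_r: float
) -> RdpAccount:
    """Overall (eps, delta_r)-DP of T composed Gaussian mechanisms.

    ``noise_to_sensitivity`` is sigma = tau/Delta, the per-iteration noise sd
    per unit of L2 sensitivity.  The conversion is evaluated at the order
    alpha_opt that minimizes it.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if noise_to_sensitivity <= 0:
        raise ValueError("noise_to_sensitivity must be positive")
    if not 0.0 < delta_r < 1.0:
        raise ValueError("delta_r must be in (0, 1)")
    sigma2 = noise_to_sensitivity**2
    log_term = math.log(1.0 / delta_r)
    alpha_opt = 1.0 + math.sqrt(2.0 * sigma2 * log_term / t)
    epsilon_opt = alpha_opt * t / (2.0 * sigma2) + log_term / (alpha_opt - 1.0)
    return RdpAccount(t, noise_to_sensitivity, delta_r, alpha_opt, epsilon_opt)


def collusion_threshold(n_sites: int) -> int:
    """Largest tolerated number of colluding sites: ceil(S/3) - 1."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return math.ceil(n_sites / 3) - 1


@dataclass(frozen=True)
class CapeAccount:
    """Privacy bookkeeping for the CAPE correlated-noise protocol."""

    n_sites: int
    n_colluders: int
    n_samples: int
    tau_s: float
    mu_z: float
    sigma_z: float
    epsilon: float
    delta: float


def _cape_mu_z(n_sites: int, n_samples: int, tau_s: float) -> float:
    """Mean of the colluding adversary's privacy-loss variable.

    Grouping of the published expression adopted here (the source typesets it
    ambiguously; see docs/methods.md):

        mu_z = S^3 / (2 tau_s^2 N^2) * [ (1+S)/(S-Sc) + 2/(S-Sc)
                                         + 9 (S-Sc) Sc^2 / (2 S (1+S) - 3 Sc^2) ]

    with Sc = ceil(S/3) - 1.  Every bracket term is positive for Sc < S and
    2S(1+S) > 3 Sc^2 (which holds for Sc <= S/3), so mu_z > 0 always.
    """
    s = n_sites
    sc = collusion_threshold(s)
    sh = s - sc
    bracket = (1.0 + s) / sh + 2.0 / sh + 9.0 * sh * sc**2 / (
        2.0 * s * (1.0 + s) - 3.0 * sc**2
    )
    return s**3 / (2.0 * tau_s**2 * n_samples**2) * bracket


def cape_delta(
    n_sites: int, n_samples: int, tau_s: float, epsilon: float
) -> tuple[float, CapeAccount]:
    """delta guaranteed by CAPE for each site at privacy level epsilon.

    The privacy-loss variable of the colluding adversary's view is modelled
    as N(mu_z, sigma_z^2) with sigma_z^2 = 2 mu_z, and the failure mass is
    the Gaussian tail bound

        delta = (2 sigma_z / (eps - mu_z)) * phi((eps - mu_z) / sigma_z),

    phi the standard normal pdf.  The result is clamped to (0, 1) with a
    warning when eps <= mu_z (no meaningful guarantee).
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    if n_sites < 3:
        raise ValueError("CAPE accounting requires at least 3 sites")
    if n_samples < 1 or tau_s <= 0:
        raise ValueError("n_samples must be >= 1 and tau_s positive")
    mu_z = _cape_mu_z(n_sites, n_samples, tau_s)
    sigma_z = math.sqrt(2.0 * mu_z)
    u = (epsilon - mu_z) / sigma_z
    if epsilon <= mu_z:
        warnings.warn(
            "epsilon <= mu_z: the CAPE tail bound degenerates; clamping delta to 1",
            UserWarning,
            stacklevel=2,
        )
        delta = 1.0
    else:
        phi = math.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
        delta = 2.0 * sigma_z / (epsilon - mu_z) * phi
        delta = min(max(delta, 0.0), 1.0)
    account = CapeAccount(
        n_sites,
        collusion_threshold(n_sites),
        n_samples,
        tau_s,
        mu_z,
        sigma_z,
        epsilon,
        delta,
    )
    return delta, account


def cape_noise_split(tau_s: float, n_sites: int) -> tuple[float, float]:
    """Split a site's target noise sd tau_s into (tau_e, tau_g).

    tau_e^2 = (1 - 1/S) tau_s^2 is carried by the correlated zero-sum term,
    tau_g^2 = tau_s^2 / S by the independent local term; the variances sum to
    tau_s^2, so each site's release is as noisy as a standalone release.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if tau_s < 0:
        raise ValueError("tau_s must be non-negative")
    tau_e = tau_s * math.sqrt(1.0 - 1.0 / n_sites)
    tau_g = tau_s / math.sqrt(n_sites)
    return tau_e, tau_g


def cape_gain(n_sites: int) -> float:
    """Variance reduction of CAPE over the conventional decentralized scheme.

    In the symmetric setting the aggregated conventional noise variance is
    tau_s^2 / S while CAPE's is tau_s^2 / S^2, so the gain is exactly S.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return float(n_sites)


def cape_H(
    site_sensitivities: Sequence[float], total_sensitivity: float, n_sites: int
) -> float:
    """Ratio tau_cape^2 / tau_pool^2 = sum_s Delta^2(N_s) / (S^3 Delta^2(N)).

    H = 1 means CAPE matches the pooled-data noise variance; this holds
    whenever Delta(N_s) = S * Delta(N), e.g. for 1/N-type sensitivities with
    equal site sizes.
    """
    sens = list(site_sensitivities)
    if not sens:
        raise ValueError("site_sensitivities must be non-empty")
    if len(sens) != n_sites:
        raise ValueError("need one sensitivity per site")
    if total_sensitivity <= 0 or any(s <= 0 for s in sens):
        raise ValueError("sensitivities must be positive")
    return sum(s * s for s in sens) / (n_sites**3 * total_sensitivity**2)
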