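"""Sensitivities of the quadratic-objective coefficients under replace-one
(bounded-DP) neighboring.

Three noise-calibration regimes are covered:

* ``gauss_fm`` -- per-order L2 sensitivities of (beta, alpha, M).  These are
  dimension-free: linear regression gives (1/N, 4/N, 1/N) and logistic
  regression (0, 1/N, 1/(8N)), where the order-2 bound uses the spectral norm
  of the rank-two update x_N x_N^T - x'_N x'_N^T.
* ``fm`` -- the single L1 sensitivity of the classic (Laplace) functional
  mechanism: (2/N)(1+D)^2 for linear, (1/N)(D^2/4 + 3D) for logistic.
* ``rlx_fm`` -- the single L2 sensitivity of the relaxed functional
  mechanism: (2/N) sqrt(1 + 4D + D^2) for linear, (1/N) sqrt(D^2/16 + D)
  for logistic.

The fm/rlx_fm values grow quadratically/linearly with D while the per-order
values do not, which is the entire utility advantage of calibrating noise per
order.  :func:`empirical_sensitivity` provides a brute-force check that the
closed forms really bound the worst case.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import objective as obj_mod
from .data import CLASSIFICATION, REGRESSION, LabeledDataset, as_rng

__all__ = [
    "SensitivityProfile",
    "gauss_fm_sensitivities",
    "fm_l1_sensitivity",
    "rlx_fm_l2_sensitivity",
    "empirical_sensitivity",
]

LINEAR = obj_mod.LINEAR
LOGISTIC = obj_mod.LOGISTIC


def _check_model(model: str) -> None:
    if model not in (LINEAR, LOGISTIC):
        raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class SensitivityProfile:
    """Sensitivity bundle for one (scheme, model, N, D) configuration."""

    scheme: str  # gauss_fm | fm | rlx_fm
    model: str
    n: int
    d: int
    per_order: tuple[float, float, float] | None = None  # gauss_fm only
    scalar: float | None = None  # fm / rlx_fm only

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "model": self.model,
                "n": self.n,
                "d": self.d,
                "per_order": list(self.per_order) if self.per_order else None,
                "scalar": self.scalar,
            }
        )


def gauss_fm_sensitivities(model: str, n: int) -> tuple[float, float, float]:
    """Per-order L2 sensitivities (Delta_0, Delta_1, Delta_2); D-independent."""
    _check_model(model)
    if n < 1:
        raise ValueError("n must be >= 1")
    if model == LINEAR:
        return (1.0 / n, 4.0 / n, 1.0 / n)
    return (0.0, 1.0 / n, 1.0 / (8.0 * n))


def fm_l1_sensitivity(model: str, n: int, d: int) -> float:
    """Scheme-wide L1 sensitivity of the classic functional mechanism."""
    _check_model(model)
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    if model == LINEAR:
        return (2.0 / n) * (1.0 + d) ** 2
    return (1.0 / n) * (d * d / 4.0 + 3.0 * d)


def rlx_fm_l2_sensitivity(model: str, n: int, d: int) -> float:
    """Scheme-wide L2 sensitivity of the relaxed functional mechanism."""
    _check_model(model)
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    if model == LINEAR:
        return (2.0 / n) * math.sqrt(1.0 + 4.0 * d + d * d)
    return (1.0 / n) * math.sqrt(d * d / 16.0 + d)


def profile(scheme: str, model: str, n: int, d: int) -> SensitivityProfile:
    """Build a :class:`SensitivityProfile` for any scheme."""
    if scheme == "gauss_fm":
        return SensitivityProfile(
            scheme, model, n, d, per_order=gauss_fm_sensitivities(model, n)
        )
    if scheme == "fm":
        return SensitivityProfile(scheme, model, n, d, scalar=fm_l1_sensitivity(model, n, d))
    if scheme == "rlx_fm":
        return SensitivityProfile(
            scheme, model, n, d, scalar=rlx_fm_l2_sensitivity(model, n, d)
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def _random_dataset(model: str, n: int, d: int, rng: np.random.Generator) -> LabeledDataset:
    x = rng.uniform(-1.0, 1.0, size=(n, d))
    x /= np.maximum(1.0, np.linalg.norm(x, axis=1))[:, None]
    if model == LINEAR:
        y = rng.uniform(-1.0, 1.0, size=n)
        return LabeledDataset(x, y, REGRESSION)
    y = rng.integers(0, 2, size=n).astype(float)
    return LabeledDataset(x, y, CLASSIFICATION)


def _replace_last(
    ds: LabeledDataset, model: str, rng: np.random.Generator
) -> LabeledDataset:
    alt = _random_dataset(model, 1, ds.n_features, rng)
    x = ds.features.copy()
    y = ds.labels.copy()
    x[-1] = alt.features[0]
    y[-1] = alt.labels[0]
    return LabeledDataset(x, y, ds.task)


def coefficient_distance(
    a: obj_mod.QuadraticObjective, b: obj_mod.QuadraticObjective, order: int
) -> float:
    """||Lambda_j(D) - Lambda_j(D')||_2 for order j.

    Order 0 is an absolute difference, order 1 a Euclidean vector norm and
    order 2 the spectral norm of the (symmetric) matrix difference, computed
    by a symmetric eigen-solve.
    """
    if order == 0:
        return abs(a.constant - b.constant)
    if order == 1:
        return float(np.linalg.norm(a.linear - b.linear))
    if order == 2:
        diff = a.quadratic - b.quadratic
        return float(np.abs(np.linalg.eigvalsh(diff)).max())
    raise ValueError("order must be 0, 1 or 2")


def empirical_sensitivity(
    model: str,
    order: int,
    n: int,
    d: int,
    trials: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Brute-force max of ||Lambda_j(D) - Lambda_j(D')||_2 over random
    replace-one neighboring pairs.

    A Monte-Carlo lower bound on the true sensitivity; it must never exceed
    the corresponding closed-form bound.
    """
    _check_model(model)
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = as_rng(seed)
    decomp = obj_mod.decompose_linear if model == LINEAR else obj_mod.decompose_logistic
    worst = 0.0
    for _ in range(trials):
        ds = _random_dataset(model, n, d, rng)
        neighbor = _replace_last(ds, model, rng)
        worst = max(worst, coefficient_distance(decomp(ds), decomp(neighbor), order))
    return worst
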