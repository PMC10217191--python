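"""Quadratic (order-2 Stone-Weierstrass) representation of regression costs.

Both supported costs are written as

    f_D(w) = beta + alpha^T w + w^T M w,

with data-dependent coefficient arrays of order 0, 1 and 2:

* linear regression (squared error, labels in [-1, 1]):
  beta = (1/N) sum y_n^2,  alpha = -(2/N) sum y_n x_n,
  M = (1/N) sum x_n x_n^T  -- an exact rewrite of the cost.

* logistic regression (cross-entropy, labels in {0, 1}): a second-order
  Taylor surrogate of log(1 + exp(z)) around z = 0 with coefficients
  log 2, 1/2 and 1/4, giving
  beta = log 2,  alpha = (1/N) sum (1/2 - y_n) x_n,
  M = (1/(8N)) sum x_n x_n^T.

The functional mechanism privatizes a fit by adding noise to (beta, alpha, M)
and minimizing the perturbed quadratic.  Noise can make M indefinite, so
:func:`repair_psd` projects its eigenvalues onto the non-negative orthant
before :func:`minimize` solves the (now bounded) problem in closed form.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CLASSIFICATION, REGRESSION, LabeledDataset

__all__ = [
    "QuadraticObjective",
    "UnboundedObjectiveError",
    "decompose_linear",
    "decompose_logistic",
    "decompose",
    "evaluate",
    "minimize",
    "symmetric_gaussian_matrix",
    "repair_psd",
    "truncate_spectrum",
    "wigner_edge",
    "sigmoid",
    "LOGISTIC_TAYLOR_COEFFS",
]

#: Taylor coefficients f^(k)(0)/k! of log(1 + exp(z)) at z = 0 for k = 0, 1, 2.
LOGISTIC_TAYLOR_COEFFS = (float(np.log(2.0)), 0.5, 0.125)

SYMMETRY_TOL = 1e-12
PSD_TOL = 1e-10

LINEAR = "linear"
LOGISTIC = "logistic"


class UnboundedObjectiveError(ValueError):
    """Raised when the quadratic objective has no finite minimizer."""


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass
class QuadraticObjective:
    """Coefficients (beta, alpha, M) of a quadratic objective in w."""

    constant: float
    linear: np.ndarray
    quadratic: np.ndarray
    model: str
    #: set by repair_psd when eigenvalue clipping actually changed M
    psd_clipped: bool = field(default=False, compare=False)
    #: set by repair_psd when *all* eigenvalues were negative (degenerate case)
    psd_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.constant = float(self.constant)
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        if self.model not in (LINEAR, LOGISTIC):
            raise ValueError(f"unknown model {self.model!r}")
        d = self.linear.shape[0]
        if self.linear.ndim != 1 or self.quadratic.shape != (d, d):
            raise ValueError("linear must be (D,) and quadratic (D, D)")
        asym = np.abs(self.quadratic - self.quadratic.T).max() if d else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"quadratic part must be symmetric (max asymmetry {asym:g})"
            )

    @property
    def dim(self) -> int:
        return self.linear.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "constant": self.constant,
                "linear": self.linear.tolist(),
                "quadratic": self.quadratic.tolist(),
                "model": self.model,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "QuadraticObjective":
        return cls(**json.loads(s))


def decompose_linear(ds: LabeledDataset) -> QuadraticObjective:
    """Exact quadratic coefficients of the mean squared-error cost."""
    if ds.task != REGRESSION:
        raise ValueError("decompose_linear requires a regression dataset")
    n = ds.n_samples
    x, y = ds.features, ds.labels
    beta = float(y @ y) / n
    alpha = -(2.0 / n) * (x.T @ y)
    quad = (x.T @ x) / n
    quad = 0.5 * (quad + quad.T)  # kill float round-off asymmetry
    return QuadraticObjective(beta, alpha, quad, LINEAR)


def decompose_logistic(ds: LabeledDataset) -> QuadraticObjective:
    """Order-2 Taylor surrogate coefficients of the logistic cross-entropy."""
    if ds.task != CLASSIFICATION:
        raise ValueError("decompose_logistic requires a classification dataset")
    n = ds.n_samples
    x, y = ds.features, ds.labels
    c0, _, c2 = LOGISTIC_TAYLOR_COEFFS
    beta = c0
    alpha = ((0.5 - y) @ x) / n
    quad = c2 * (x.T @ x) / n
    quad = 0.5 * (quad + quad.T)
    return QuadraticObjective(beta, alpha, quad, LOGISTIC)


def decompose(ds: LabeledDataset) -> QuadraticObjective:
    """Dispatch on the dataset's task."""
    if ds.task == REGRESSION:
        return decompose_linear(ds)
    return decompose_logistic(ds)


def evaluate(obj: QuadraticObjective, w: np.ndarray) -> float:
    """beta + alpha^T w + w^T M w."""
    w = np.asarray(w, dtype=float)
    if w.shape != (obj.dim,):
        raise ValueError(f"w must have shape ({obj.dim},), got {w.shape}")
    return float(obj.constant + obj.linear @ w + w @ obj.quadratic @ w)


def minimize(obj: QuadraticObjective) -> np.ndarray:
    """Closed-form minimizer of a PSD quadratic: solve 2 M w = -alpha.

    Uses the pseudoinverse, so rank-deficient M returns the minimum-norm
    solution.  Raises :class:`UnboundedObjectiveError` when M = 0 with a
    non-zero linear term (the objective decreases without bound).
    """
    if not (np.isfinite(obj.linear).all() and np.isfinite(obj.quadratic).all()):
        raise ValueError("objective has non-finite coefficients")
    m2 = 2.0 * obj.quadratic
    if np.allclose(m2, 0.0):
        if np.allclose(obj.linear, 0.0):
            return np.zeros(obj.dim)
        raise UnboundedObjectiveError(
            "quadratic part is zero with a non-zero linear term; "
            "the objective is unbounded below"
        )
    return -np.linalg.pinv(m2, hermitian=True) @ obj.linear


def symmetric_gaussian_matrix(
    d: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric matrix with i.i.d. N(0, sd^2) entries on and above the diagonal.

    Strictly-upper entries are mirrored below, so each independent draw is
    made exactly once and the result is exactly symmetric.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    upper = np.triu(rng.normal(0.0, sd, size=(d, d)))
    return upper + np.triu(upper, k=1).T


def wigner_edge(d: int, entry_sd: float) -> float:
    """Spectral radius of a d x d symmetric noise matrix with entry sd.

    Eigenvalues of such a matrix concentrate in [-2 sd sqrt(d), 2 sd sqrt(d)];
    eigenvalues of a noisy Gram matrix below this edge are indistinguishable
    from pure noise.
    """
    return 2.0 * entry_sd * math.sqrt(d)


def truncate_spectrum(obj: QuadraticObjective, floor: float) -> QuadraticObjective:
    """Zero out eigenvalues of the quadratic part that sit below ``floor``.

    Numerical stabilization for minimizing noise-perturbed quadratics: after
    PSD repair, eigenvalues below the noise level carry no curvature signal,
    and inverting them amplifies both signal and noise without bound.  The
    largest eigenvalue is always retained so the minimizer stays defined even
    when noise dominates the whole spectrum.  ``floor <= 0`` is the identity,
    so noise-free fits are untouched.
    """
    if floor <= 0.0:
        return obj
    eigvals, eigvecs = np.linalg.eigh(obj.quadratic)
    cut = min(floor, eigvals.max())
    kept = np.where(eigvals >= cut, eigvals, 0.0)
    if np.array_equal(kept, eigvals):
        return obj
    quad = (eigvecs * kept) @ eigvecs.T
    quad = 0.5 * (quad + quad.T)
    return QuadraticObjective(
        obj.constant,
        obj.linear,
        quad,
        obj.model,
        psd_clipped=obj.psd_clipped,
        psd_warning=obj.psd_warning,
    )


def repair_psd(obj: QuadraticObjective) -> QuadraticObjective:
    """Project the quadratic part's eigenvalues onto the non-negative orthant.

    The constant and linear parts are untouched.  When every eigenvalue is
    negative the projection yields M = 0 and the minimizer is typically
    undefined; the result is flagged (``psd_warning``) and a RuntimeWarning
    is emitted -- this degenerate case has no principled resolution here.
    """
    eigvals, eigvecs = np.linalg.eigh(obj.quadratic)
    if eigvals.min() >= 0.0:
        return QuadraticObjective(
            obj.constant, obj.linear, obj.quadratic, obj.model
        )
    all_negative = bool(eigvals.max() < 0.0)
    if all_negative:
        warnings.warn(
            "all eigenvalues of the noisy quadratic part are negative; "
            "projection yields a zero matrix and the objective may be unbounded",
            RuntimeWarning,
            stacklevel=2,
        )
    clipped = np.clip(eigvals, 0.0, None)
    quad = (eigvecs * clipped) @ eigvecs.T
    quad = 0.5 * (quad + quad.T)
    return QuadraticObjective(
        obj.constant,
        obj.linear,
        quad,
        obj.model,
        psd_clipped=True,
        psd_warning=all_negative,
    )
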