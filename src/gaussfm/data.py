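"""Dataset containers, preprocessing, synthesis, splitting and site partitioning.

The privacy analysis of the functional mechanism rests on two normalization
assumptions: every feature vector has Euclidean norm at most 1, and labels lie
in [-1, 1] (regression) or {0, 1} (classification).  :func:`preprocess` is the
single place where those assumptions are enforced; every fitting routine in
this package expects its input to have passed through it (or through one of
the synthetic generators, which produce compliant data by construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SiteCollection",
    "LabelTransform",
    "load_csv",
    "preprocess",
    "synth_linear",
    "synth_logistic",
    "split",
    "partition_sites",
]

#: slack allowed on the unit-norm constraint when validating
NORM_TOL = 1e-9

REGRESSION = "regression"
CLASSIFICATION = "classification"
_TASKS = (REGRESSION, CLASSIFICATION)


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed (or an existing Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class LabeledDataset:
    """N samples (x_n, y_n) with x_n the rows of ``features``.

    Construction checks only structural soundness (shapes, finiteness, binary
    labels for classification).  The norm/range assumptions required by the
    privacy analysis are checked by :meth:`validate` and established by
    :func:`preprocess`.
    """

    features: np.ndarray
    labels: np.ndarray
    task: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.task not in _TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {_TASKS}")
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array (samples in rows)")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels must be a 1-D array with one entry per row")
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("dataset needs at least one sample and one feature")
        if not np.isfinite(self.features).all() or not np.isfinite(self.labels).all():
            raise ValueError("features/labels contain NaN or infinite values")
        if self.task == CLASSIFICATION and not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("classification labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.features, axis=1)

    def validate(self) -> "LabeledDataset":
        """Assert the normalization assumptions; return self for chaining."""
        if self.row_norms().max() > 1.0 + NORM_TOL:
            raise ValueError(
                "feature rows must have L2 norm <= 1; run preprocess() first"
            )
        if self.task == REGRESSION:
            if self.labels.min() < -1.0 - NORM_TOL or self.labels.max() > 1.0 + NORM_TOL:
                raise ValueError("regression labels must lie in [-1, 1]")
        return self

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.features[idx], self.labels[idx], self.task)


@dataclass
class SiteCollection:
    """An ordered collection of per-site datasets sharing task and dimension."""

    sites: list[LabeledDataset]
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("site collection must hold at least one site")
        d0, t0 = self.sites[0].n_features, self.sites[0].task
        for s in self.sites:
            if s.n_features != d0 or s.task != t0:
                raise ValueError("all sites must share dimension and task")
        if self.symmetric:
            counts = {s.n_samples for s in self.sites}
            if len(counts) != 1:
                raise ValueError("symmetric collection requires equal site sizes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_sizes(self) -> list[int]:
        return [s.n_samples for s in self.sites]

    @property
    def total_samples(self) -> int:
        return sum(self.site_sizes)

    @property
    def n_features(self) -> int:
        return self.sites[0].n_features

    @property
    def task(self) -> str:
        return self.sites[0].task

    def pooled(self) -> LabeledDataset:
        return LabeledDataset(
            np.vstack([s.features for s in self.sites]),
            np.concatenate([s.labels for s in self.sites]),
            self.task,
        )


@dataclass
class LabelTransform:
    """Affine map fitted on training labels: [y_min, y_max] -> [-1, 1].

    Applying the transform to unseen labels clips to [-1, 1], so a test split
    mapped with a train-fitted transform always satisfies the label range the
    sensitivity analysis assumes.  Identity for classification.
    """

    y_min: float = -1.0
    y_max: float = 1.0
    identity: bool = False

    def apply(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.identity:
            return y.copy()
        scaled = 2.0 * (y - self.y_min) / (self.y_max - self.y_min) - 1.0
        return np.clip(scaled, -1.0, 1.0)

    def to_json(self) -> str:
        return json.dumps(
            {"y_min": self.y_min, "y_max": self.y_max, "identity": self.identity}
        )

    @classmethod
    def from_json(cls, s: str) -> "LabelTransform":
        return cls(**json.loads(s))


def load_csv(path: str | Path, label_column: str, task: str) -> LabeledDataset:
    """Read a headered CSV into a raw (not yet normalized) dataset.

    Every non-label column is taken as a feature; all cells must be numeric.
    Row order is preserved.  The normalization invariants are *not* enforced
    here -- call :func:`preprocess` next.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    if label_column not in frame.columns:
        raise ValueError(
            f"label column {label_column!r} not in CSV columns {list(frame.columns)}"
        )
    feature_cols = [c for c in frame.columns if c != label_column]
    if not feature_cols:
        raise ValueError("CSV must contain at least one feature column")
    for col in [label_column, *feature_cols]:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"non-numeric or missing cell at row {row}, column {col!r}")
    return LabeledDataset(
        frame[feature_cols].to_numpy(dtype=float),
        frame[label_column].to_numpy(dtype=float),
        task,
    )


def save_csv(ds: LabeledDataset, path: str | Path, label_column: str = "y") -> None:
    """Write a dataset back to CSV (inverse of :func:`load_csv`)."""
    cols = {f"x{d}": ds.features[:, d] for d in range(ds.n_features)}
    cols[label_column] = ds.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def preprocess(
    raw: LabeledDataset, transform: LabelTransform | None = None
) -> tuple[LabeledDataset, LabelTransform]:
    """Enforce the norm/range assumptions the privacy analysis requires.

    Each feature row is scaled by 1/max(1, ||x||2), which caps the norm at 1
    without touching already-compliant rows and needs no train statistics, so
    it is safe to apply to unseen data.  Regression labels are min-max mapped
    to [-1, 1]; the fitted :class:`LabelTransform` is returned so the same map
    (with clipping) can be reapplied to a held-out split.  Pass ``transform``
    to reuse a previously fitted map instead of fitting a new one.
    """
    norms = raw.row_norms()
    scale = np.maximum(1.0, norms)
    features = raw.features / scale[:, None]

    if raw.task == CLASSIFICATION:
        tf = transform if transform is not None else LabelTransform(identity=True)
        labels = tf.apply(raw.labels)
    else:
        if transform is None:
            lo, hi = float(raw.labels.min()), float(raw.labels.max())
            if hi - lo <= 0:
                raise ValueError(
                    "regression labels are constant; min-max scaling undefined"
                )
            tf = LabelTransform(y_min=lo, y_max=hi)
        else:
            tf = transform
        labels = tf.apply(raw.labels)

    return LabeledDataset(features, labels, raw.task).validate(), tf


def _draw_features(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    # i.i.d. uniform on [-1,1]^D, then per-row scaling onto the unit ball;
    # any bounded draw satisfies the sensitivity assumptions.
    x = rng.uniform(-1.0, 1.0, size=(n, d))
    norms = np.linalg.norm(x, axis=1)
    return x / np.maximum(1.0, norms)[:, None]


def synth_linear(
    n: int,
    d: int,
    w_true: Sequence[float] | np.ndarray,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> LabeledDataset:
    """Linear-model data: y = x^T w_true + N(0, noise_sd^2), clipped to [-1, 1]."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    w_true = np.asarray(w_true, dtype=float)
    if w_true.shape != (d,):
        raise ValueError(f"w_true must have shape ({d},)")
    rng = as_rng(seed)
    x = _draw_features(n, d, rng)
    y = x @ w_true + rng.normal(0.0, noise_sd, size=n)
    return LabeledDataset(x, np.clip(y, -1.0, 1.0), REGRESSION).validate()


def synth_logistic(
    n: int,
    d: int,
    w_true: Sequence[float] | np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> LabeledDataset:
    """Logistic-model data: y ~ Bernoulli(sigmoid(x^T w_true))."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    w_true = np.asarray(w_true, dtype=float)
    if w_true.shape != (d,):
        raise ValueError(f"w_true must have shape ({d},)")
    rng = as_rng(seed)
    x = _draw_features(n, d, rng)
    p = 1.0 / (1.0 + np.exp(-(x @ w_true)))
    y = (rng.uniform(size=n) < p).astype(float)
    return LabeledDataset(x, y, CLASSIFICATION).validate()


def split(
    ds: LabeledDataset,
    test_fraction: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Shuffled disjoint train/test split; |test| = round(N * test_fraction)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if ds.n_samples < 2:
        raise ValueError("need at least two samples to split")
    rng = as_rng(seed)
    perm = rng.permutation(ds.n_samples)
    n_test = int(round(ds.n_samples * test_fraction))
    n_test = min(max(n_test, 1), ds.n_samples - 1)
    return ds.subset(perm[n_test:]), ds.subset(perm[:n_test])


def partition_sites(
    ds: LabeledDataset,
    n_sites: int,
    seed: int | np.random.Generator | None = None,
) -> SiteCollection:
    """Shuffle and split into ``n_sites`` equal disjoint sites.

    In the symmetric setting each site holds floor(N/S) samples; any remainder
    rows are dropped.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites > ds.n_samples:
        raise ValueError("more sites than samples")
    if n_sites == 1:
        return SiteCollection([ds])
    rng = as_rng(seed)
    perm = rng.permutation(ds.n_samples)
    per_site = ds.n_samples // n_sites
    sites = [
        ds.subset(perm[s * per_site : (s + 1) * per_site]) for s in range(n_sites)
    ]
    return SiteCollection(sites)
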