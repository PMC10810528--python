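"""Seeded synthetic datasets with known ground-truth local structure.

Real use cases of the method are black-box property predictors (molecular
vapour-pressure regressors, jet classifiers) whose behaviour is locally
linear in interpretable features.  The generators here emulate exactly
that structure — several linear regimes plus additive noise — so that the
true local models and regime memberships are known and recovery can be
tested.  What they deliberately do *not* emulate: realistic descriptor
correlations, heavy-tailed targets, or label noise from a trained
black box.

All randomness flows from one master seed through named substreams, so
every experiment replays from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, LINEAR, LOGISTIC

__all__ = [
    "RegimeSpec",
    "SyntheticData",
    "generate_piecewise_1d",
    "generate_multivariate_regimes",
    "permute_targets",
    "substream",
]

_STREAMS = ("data", "init", "permutation", "resampling")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child generator of a master seed (replayable substreams)."""
    if name not in _STREAMS:
        raise ValueError(f"unknown stream {name!r}; use one of {_STREAMS}")
    root = np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(name),))
    return np.random.default_rng(root)


@dataclass
class RegimeSpec:
    """Parameters of a piecewise-linear (or -logistic) generating process."""

    n: int = 400
    m: int = 1
    n_regimes: int = 2
    coefficients: np.ndarray | None = None  # (K, m+1), intercept last
    noise_sd: float = 0.1
    seed: int = 0
    task: str = "regression"

    def __post_init__(self):
        if self.n_regimes < 1:
            raise ValueError("need at least one regime")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticData:
    """Raw generated data plus the ground truth behind it."""

    X: np.ndarray  # (n, m) raw features
    y: np.ndarray  # (n,) raw target (or probability for classification)
    labels: np.ndarray  # (n,) true regime index
    coefficients: np.ndarray  # (K, m+1) true raw-scale models, intercept last
    task: str = "regression"
    extras: dict = field(default_factory=dict)

    def to_dataset(self, standardize_target: bool | str = "auto") -> Dataset:
        family = LINEAR if self.task == "regression" else LOGISTIC
        return Dataset.from_raw(
            self.X, self.y, family=family, standardize_target=standardize_target
        )

    def standardized_coefficients(self, dataset: Dataset) -> np.ndarray:
        """True models re-expressed in the dataset's standardized units.

        For ``y_s = (y - my)/sy`` and ``x_s = (x - mx)/sx`` the raw model
        ``y = a.x + b`` becomes ``y_s = (a*sx/sy).x_s + (a.mx + b - my)/sy``.
        """
        a = self.coefficients[:, :-1]
        b = self.coefficients[:, -1]
        sx, mx = dataset.x_scale, dataset.x_mean
        if dataset.y_mean is not None:
            sy, my = float(dataset.y_scale[0]), float(dataset.y_mean[0])
        else:
            sy, my = 1.0, 0.0
        a_s = a * sx[None, :] / sy
        b_s = (a @ mx + b - my) / sy
        return np.column_stack([a_s, b_s])


# ----------------------------------------------------------------------
def generate_piecewise_1d(
    n: int = 400,
    *,
    slopes=(-1.0, 1.0),
    intercepts=None,
    breakpoints=(0.0,),
    noise_sd: float = 0.1,
    x_range=(-2.0, 2.0),
    seed: int = 0,
) -> SyntheticData:
    """1-D piecewise-linear regression data.

    ``x ~ Uniform(x_range)``; regime k is the interval between consecutive
    breakpoints and ``y = slopes[k] * x + intercepts[k] + eps`` with
    ``eps ~ N(0, noise_sd^2)``.  The default (slopes -1/+1, breakpoint 0,
    zero intercepts) is the noisy absolute-value function: two local
    explanations suffice for a globally nonlinear target.
    """
    slopes = np.asarray(slopes, dtype=float)
    K = slopes.size
    if intercepts is None:
        intercepts = np.zeros(K)
    intercepts = np.asarray(intercepts, dtype=float)
    breakpoints = np.asarray(breakpoints, dtype=float)
    if breakpoints.size != K - 1:
        raise ValueError("need exactly n_regimes - 1 breakpoints")
    rng = substream(seed, "data")
    x = rng.uniform(x_range[0], x_range[1], size=n)
    labels = np.searchsorted(breakpoints, x)
    y = slopes[labels] * x + intercepts[labels]
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=n)
    coef = np.column_stack([slopes, intercepts])
    return SyntheticData(
        X=x[:, None], y=y, labels=labels, coefficients=coef,
        task="regression",
        extras={"breakpoints": breakpoints, "noise_sd": noise_sd, "seed": seed},
    )


def generate_multivariate_regimes(
    n: int = 400,
    m: int = 4,
    n_regimes: int = 3,
    *,
    coefficients: np.ndarray | None = None,
    centroid_scale: float = 3.0,
    noise_sd: float = 0.1,
    task: str = "regression",
    seed: int = 0,
) -> SyntheticData:
    """Multi-feature regime data for testing coefficient clustering.

    Features are drawn from a K-component Gaussian mixture (unit-variance
    components around seeded centroids); the regime of an item is the
    nearest centroid; the target is the regime's linear model plus noise
    (regression) or the sigmoid of it (classification, soft labels).
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    rng = substream(seed, "data")
    K = n_regimes
    centroids = rng.normal(scale=centroid_scale, size=(K, m))
    if coefficients is None:
        coefficients = rng.normal(scale=1.0, size=(K, m + 1))
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (K, m + 1):
        raise ValueError("coefficients must be (n_regimes, m+1)")
    comp = rng.integers(K, size=n)
    X = centroids[comp] + rng.normal(size=(n, m))
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    lin = (coefficients[labels, :-1] * X).sum(axis=1) + coefficients[labels, -1]
    if task == "regression":
        y = lin + (rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0)
    else:
        logits = lin + (rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0)
        y = 1.0 / (1.0 + np.exp(-logits))
    return SyntheticData(
        X=X, y=y, labels=labels, coefficients=coefficients, task=task,
        extras={"centroids": centroids, "noise_sd": noise_sd, "seed": seed},
    )


def generate(spec: RegimeSpec) -> SyntheticData:
    """Generate from a :class:`RegimeSpec` (dispatches on ``m``)."""
    if spec.m == 1 and spec.task == "regression":
        if spec.coefficients is not None:
            coef = np.asarray(spec.coefficients, dtype=float)
            slopes, intercepts = coef[:, 0], coef[:, 1]
        else:
            slopes = np.linspace(-1, 1, spec.n_regimes) if spec.n_regimes > 1 else np.array([1.0])
            intercepts = None
        bps = np.linspace(-2, 2, spec.n_regimes + 1)[1:-1]
        return generate_piecewise_1d(
            spec.n, slopes=slopes, intercepts=intercepts, breakpoints=bps,
            noise_sd=spec.noise_sd, seed=spec.seed,
        )
    return generate_multivariate_regimes(
        spec.n, spec.m, spec.n_regimes, coefficients=spec.coefficients,
        noise_sd=spec.noise_sd, task=spec.task, seed=spec.seed,
    )


# ----------------------------------------------------------------------
def permute_targets(data, seed: int = 0):
    """Return a copy with the target rows permuted by a seeded uniform
    random permutation (features untouched, target multiset preserved)."""
    rng = substream(seed, "permutation")
    if isinstance(data, Dataset):
        perm = rng.permutation(data.n)
        out = data.subset(np.arange(data.n))
        out.Y = data.Y[perm]
        return out
    if isinstance(data, SyntheticData):
        perm = rng.permutation(data.y.shape[0])
        return SyntheticData(
            X=data.X.copy(), y=data.y[perm], labels=data.labels.copy(),
            coefficients=data.coefficients.copy(), task=data.task,
            extras=dict(data.extras),
        )
    y = np.asarray(data)
    return y[rng.permutation(y.shape[0])]
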