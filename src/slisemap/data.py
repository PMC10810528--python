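"""Tabular dataset container with the standardization used throughout.

Features are normalised to zero mean and unit variance (which makes the
lasso/ridge penalties on the local-model coefficients scale-free) and a
constant-1 intercept column is appended, so local linear models of width
``m + 1`` include an intercept.  Regression targets are standardized by
default as well; classification targets are probabilities and are left
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dataset"]

_STD_TOL = 1e-8

LINEAR = "linear_regression"
LOGISTIC = "logistic_regression"
_FAMILIES = (LINEAR, LOGISTIC)


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"expected a 1-D or 2-D array, got shape {a.shape}")
    return a


@dataclass
class Dataset:
    """Standardized feature matrix (intercept appended) and targets.

    Attributes
    ----------
    X : (n, m+1) array
        Standardized features with a trailing constant-1 intercept column.
    Y : (n, o) array
        Targets; standardized for regression (if ``y_mean`` is set),
        probabilities in [0, 1] for classification.
    feature_names : list of str
        Names of the ``m`` original features plus ``"intercept"``.
    x_mean, x_scale : (m,) arrays
        Per-column standardization parameters of the original features.
    y_mean, y_scale : (o,) arrays or None
        Target standardization parameters; None when the target was not
        standardized (classification, or ``standardize_target=False``).
    family : str
        Local-model family the targets are meant for.
    """

    X: np.ndarray
    Y: np.ndarray
    feature_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray | None = None
    y_scale: np.ndarray | None = None
    family: str = LINEAR
    target_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        """Number of original (pre-intercept) features."""
        return self.X.shape[1] - 1

    @property
    def o(self) -> int:
        return self.Y.shape[1]

    @property
    def p(self) -> int:
        """Coefficients per local model."""
        if self.family == LOGISTIC:
            return self.m + 1
        return (self.m + 1) * self.o

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = _as_2d(self.Y)
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y have different numbers of rows")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 data items")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("X/Y contain missing or non-finite values")
        if not np.allclose(self.X[:, -1], 1.0):
            raise ValueError("last column of X must be the constant-1 intercept")
        if self.family == LOGISTIC:
            if self.Y.shape[1] != 1:
                raise ValueError("logistic targets must be a single probability column")
            if ((self.Y < 0) | (self.Y > 1)).any():
                raise ValueError("logistic targets must be probabilities in [0, 1]")

    # ------------------------------------------------------------------
    @classmethod
    def from_raw(
        cls,
        X_raw,
        Y_raw,
        *,
        feature_names: list[str] | None = None,
        target_names: list[str] | None = None,
        family: str = LINEAR,
        standardize_target: bool | str = "auto",
    ) -> "Dataset":
        """Standardize raw features, append an intercept and wrap up.

        ``standardize_target="auto"`` standardizes regression targets and
        leaves classification probabilities alone.
        """
        X_raw = _as_2d(X_raw)
        Y_raw = _as_2d(Y_raw)
        n, m = X_raw.shape
        if n != Y_raw.shape[0]:
            raise ValueError("X and Y have different numbers of rows")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(m)]
        if len(feature_names) != m:
            raise ValueError("feature_names length does not match X width")
        bad = ~np.isfinite(X_raw).all(axis=1) | ~np.isfinite(Y_raw).all(axis=1)
        if bad.any():
            rows = np.flatnonzero(bad)[:20].tolist()
            raise ValueError(f"missing/non-finite values in rows {rows}")

        x_mean = X_raw.mean(axis=0)
        x_scale = X_raw.std(axis=0)
        dead = np.flatnonzero(x_scale < _STD_TOL)
        if dead.size:
            names = [feature_names[j] for j in dead]
            raise ValueError(f"constant feature column(s) cannot be standardized: {names}")
        Xs = (X_raw - x_mean) / x_scale
        X = np.hstack([Xs, np.ones((n, 1))])

        if standardize_target == "auto":
            standardize_target = family == LINEAR
        y_mean = y_scale = None
        Y = Y_raw.copy()
        if standardize_target:
            if family == LOGISTIC:
                raise ValueError("probability targets cannot be standardized")
            y_mean = Y_raw.mean(axis=0)
            y_scale = Y_raw.std(axis=0)
            if (y_scale < _STD_TOL).any():
                raise ValueError("constant target cannot be standardized")
            Y = (Y_raw - y_mean) / y_scale

        if target_names is None:
            target_names = [f"y{j}" for j in range(Y.shape[1])]
        return cls(
            X=X,
            Y=Y,
            feature_names=list(feature_names) + ["intercept"],
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=y_mean,
            y_scale=y_scale,
            family=family,
            target_names=list(target_names),
        )

    # ------------------------------------------------------------------
    def raw_features(self) -> np.ndarray:
        """Invert the standardization (drops the intercept column)."""
        return self.X[:, :-1] * self.x_scale + self.x_mean

    def raw_targets(self) -> np.ndarray:
        if self.y_mean is None:
            return self.Y.copy()
        return self.Y * self.y_scale + self.y_mean

    def subset(self, idx) -> "Dataset":
        """Row subset sharing this dataset's standardization parameters."""
        idx = np.asarray(idx)
        return Dataset(
            X=self.X[idx],
            Y=self.Y[idx],
            feature_names=list(self.feature_names),
            x_mean=self.x_mean,
            x_scale=self.x_scale,
            y_mean=self.y_mean,
            y_scale=self.y_scale,
            family=self.family,
            target_names=list(self.target_names),
        )
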