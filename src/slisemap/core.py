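r"""The supervised-embedding objective and its building blocks.

The method places every data item at a point :math:`z_i \in R^d` and gives
it an interpretable local model :math:`f_i` (row :math:`B_i` of the
coefficient matrix), minimising

.. math::

    L = \sum_i \sum_j \frac{e^{-\|z_i - z_j\|_2}}{\sum_k e^{-\|z_i-z_k\|_2}}
        \, l(f_i(x_j), y_j)
        + \sum_{i,j} (\lambda_{lasso} |B_{ij}| + \lambda_{ridge} B_{ij}^2)

subject to the mean-squared-radius constraint
:math:`\sum_{i,k} z_{ik}^2 / n = r^2`, which pins the scale of the softmax
kernel (without it the loss is trivially minimised by scattering the
embedding to infinity).  Items end up close together exactly when their
local models predict each other's targets well.

The loss ``l`` is the squared error for linear local models and the squared
Hellinger distance between predicted and target class probabilities for
logistic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data import Dataset, LINEAR, LOGISTIC

__all__ = [
    "Embedding",
    "LocalModelBank",
    "SlisemapSolution",
    "kernel_weights",
    "local_predict",
    "pointwise_loss",
    "pairwise_local_loss",
    "penalty",
    "slisemap_loss",
    "slisemap_loss_grad",
    "project_to_radius",
]

_EPS = 1e-12
_CLIP = 1e-9  # probability clip for Hellinger gradients


# ----------------------------------------------------------------------
# kernel
# ----------------------------------------------------------------------
def kernel_weights(Z: np.ndarray, *, squared: bool = False) -> np.ndarray:
    """Row-stochastic softmax weights over embedding distances.

    ``W[i, j] = exp(-g(d_ij)) / sum_k exp(-g(d_ik))`` with
    ``g(d) = d`` (default) or ``d**2`` (``squared=True``).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.isfinite(Z).all():
        raise FloatingPointError("non-finite embedding (diverged optimisation?)")
    D = cdist(Z, Z)
    G = D**2 if squared else D
    # subtract the row minimum (=0 on the diagonal) for numeric safety
    E = np.exp(-G)
    return E / E.sum(axis=1, keepdims=True)


def project_to_radius(Z: np.ndarray, r: float) -> np.ndarray:
    """Rescale ``Z`` so that the mean squared row norm equals ``r**2``."""
    Z = np.asarray(Z, dtype=float)
    rms = np.sqrt((Z**2).sum() / Z.shape[0])
    if rms < _EPS:
        raise ValueError("all-zero embedding cannot be projected; re-initialise")
    return Z * (r / rms)


# ----------------------------------------------------------------------
# local models
# ----------------------------------------------------------------------
def local_predict(b_row: np.ndarray, X: np.ndarray, family: str, o: int = 1) -> np.ndarray:
    """Predictions of one local model on all rows of ``X``.

    Linear models return an ``(n, o)`` matrix ``X @ B`` (coefficients laid
    out output-major).  Logistic models return ``(n, 2)`` class
    probabilities ``[1 - p, p]``.
    """
    b_row = np.asarray(b_row, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    m1 = X.shape[1]
    if family == LINEAR:
        if b_row.size != m1 * o:
            raise ValueError(f"expected {m1 * o} coefficients, got {b_row.size}")
        return X @ b_row.reshape(o, m1).T
    if family == LOGISTIC:
        if b_row.size != m1:
            raise ValueError(f"expected {m1} coefficients, got {b_row.size}")
        p = _sigmoid(X @ b_row)
        return np.column_stack([1.0 - p, p])
    raise ValueError(f"unknown family {family!r}")


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def pointwise_loss(yhat: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    """Per-item loss between predictions and targets.

    Squared error (summed over outputs) for regression; squared Hellinger
    distance between binary class distributions for classification, where
    both arguments may be a single positive-class probability or a
    two-column distribution.
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if family == LINEAR:
        d = np.atleast_2d(yhat.reshape(yhat.shape[0], -1) - y.reshape(y.shape[0], -1))
        return (d**2).sum(axis=1)
    if family == LOGISTIC:
        p = _pos_prob(yhat)
        q = _pos_prob(y)
        if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1)).any():
            raise ValueError("classification losses need probabilities in [0, 1]")
        return _hellinger2(p, q)
    raise ValueError(f"unknown family {family!r}")


def _pos_prob(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 2 and a.shape[1] == 2:
        return a[:, 1]
    return a.reshape(-1)


def _hellinger2(p, q):
    """Squared Hellinger distance on the 2-class simplex; max value 2."""
    return (np.sqrt(p) - np.sqrt(q)) ** 2 + (np.sqrt(1 - p) - np.sqrt(1 - q)) ** 2


# ----------------------------------------------------------------------
# pairwise loss matrix L[i, j] = l(f_i(x_j), y_j)
# ----------------------------------------------------------------------
def pairwise_local_loss(B: np.ndarray, X: np.ndarray, Y: np.ndarray, family: str) -> np.ndarray:
    """Loss of every local model on every item, shape (n_models, n_items)."""
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m1 = X.shape
    o = Y.shape[1]
    if family == LINEAR:
        if o == 1:
            R = B @ X.T - Y[:, 0][None, :]
            return R**2
        Br = B.reshape(B.shape[0], o, m1)
        P = np.einsum("iom,jm->ijo", Br, X)
        return ((P - Y[None, :, :]) ** 2).sum(axis=2)
    if family == LOGISTIC:
        P = _sigmoid(B @ X.T)
        q = Y[:, 0][None, :]
        return _hellinger2(P, q)
    raise ValueError(f"unknown family {family!r}")


def _pairwise_loss_and_bgrad(B, X, Y, family, W):
    """Loss matrix plus the gradient of ``sum(W * L)`` w.r.t. ``B``."""
    n, m1 = X.shape
    o = Y.shape[1]
    if family == LINEAR:
        if o == 1:
            R = B @ X.T - Y[:, 0][None, :]
            return R**2, 2.0 * (W * R) @ X
        Br = B.reshape(B.shape[0], o, m1)
        P = np.einsum("iom,jm->ijo", Br, X)
        R = P - Y[None, :, :]
        L = (R**2).sum(axis=2)
        gB = 2.0 * np.einsum("ij,ijo,jm->iom", W, R, X).reshape(B.shape)
        return L, gB
    if family == LOGISTIC:
        T = B @ X.T
        P = _sigmoid(T)
        q = Y[:, 0][None, :]
        L = _hellinger2(P, q)
        Pc = np.clip(P, _CLIP, 1.0 - _CLIP)
        dL_dt = (np.sqrt((1.0 - q) / (1.0 - Pc)) - np.sqrt(q / Pc)) * P * (1.0 - P)
        gB = (W * dL_dt) @ X
        return L, gB
    raise ValueError(f"unknown family {family!r}")


# ----------------------------------------------------------------------
# penalties and total loss
# ----------------------------------------------------------------------
def _intercept_mask(p: int, m1: int, family: str) -> np.ndarray:
    """Boolean mask over the p coefficients marking intercept entries."""
    mask = np.zeros(p, dtype=bool)
    if family == LOGISTIC:
        mask[m1 - 1] = True
    else:
        mask.reshape(-1, m1)[:, m1 - 1] = True
    return mask


def penalty(B, lasso, ridge, *, penalize_intercept=True, m1=None, family=LINEAR):
    """Elastic-net style penalty ``sum(lasso*|B| + ridge*B**2)``."""
    B = np.asarray(B, dtype=float)
    if penalize_intercept:
        Bp = B
    else:
        mask = ~_intercept_mask(B.shape[1], m1, family)
        Bp = B[:, mask]
    return lasso * np.abs(Bp).sum() + ridge * (Bp**2).sum()


def slisemap_loss(
    Z,
    B,
    X,
    Y,
    *,
    family: str = LINEAR,
    lasso: float = 0.0,
    ridge: float = 0.0,
    squared_kernel: bool = False,
    penalize_intercept: bool = True,
) -> float:
    """Value of the full objective at the given embedding and models."""
    W = kernel_weights(Z, squared=squared_kernel)
    L = pairwise_local_loss(B, X, Y, family)
    pen = penalty(
        np.asarray(B, float), lasso, ridge,
        penalize_intercept=penalize_intercept, m1=X.shape[1], family=family,
    )
    return float((W * L).sum() + pen)


def slisemap_loss_grad(
    Z,
    B,
    X,
    Y,
    *,
    family: str = LINEAR,
    lasso: float = 0.0,
    ridge: float = 0.0,
    squared_kernel: bool = False,
    penalize_intercept: bool = True,
):
    """Loss plus analytic gradients w.r.t. ``Z`` and ``B``.

    The lasso term uses the sign subgradient (0 at exactly-zero entries).
    """
    Z = np.asarray(Z, dtype=float)
    B = np.asarray(B, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = Z.shape[0]
    if not np.isfinite(Z).all():
        raise FloatingPointError("non-finite embedding (diverged optimisation?)")

    D = cdist(Z, Z)
    G = D**2 if squared_kernel else D
    E = np.exp(-G)
    s = E.sum(axis=1, keepdims=True)
    W = E / s

    L, gB = _pairwise_loss_and_bgrad(B, X, Y, family, W)
    data_loss = float((W * L).sum())

    # dL/dg_ab = W_ab * (<W_a, L_a> - L_ab); chain to distances then to Z
    row_mean = (W * L).sum(axis=1, keepdims=True)
    GD = W * (row_mean - L)
    if squared_kernel:
        GD = GD * 2.0 * D
    # d d_ab / d z_a = (z_a - z_b) / d_ab  (0 at coincident points)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(D > _EPS, (GD + GD.T) / D, 0.0)
    np.fill_diagonal(C, 0.0)
    gZ = Z * C.sum(axis=1, keepdims=True) - C @ Z

    mask = np.ones(B.shape[1], dtype=bool)
    if not penalize_intercept:
        mask = ~_intercept_mask(B.shape[1], X.shape[1], family)
    pen = lasso * np.abs(B[:, mask]).sum() + ridge * (B[:, mask] ** 2).sum()
    gB = gB.copy()
    gB[:, mask] += lasso * np.sign(B[:, mask]) + 2.0 * ridge * B[:, mask]

    return data_loss + float(pen), gZ, gB


# ----------------------------------------------------------------------
# solution containers
# ----------------------------------------------------------------------
@dataclass
class Embedding:
    """Low-dimensional coordinates under the mean-squared-radius constraint."""

    Z: np.ndarray
    d: int = 2
    r: float = 3.5
    squared_kernel: bool = False

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != self.d:
            raise ValueError("Z must be (n, d)")

    def radius_violation(self) -> float:
        """Relative deviation of the mean squared norm from r**2."""
        msq = (self.Z**2).sum() / self.Z.shape[0]
        return abs(msq - self.r**2) / self.r**2


@dataclass
class LocalModelBank:
    """Per-item interpretable models: row i parametrises f_i."""

    B: np.ndarray
    family: str = LINEAR
    lambda_lasso: float = 0.0
    lambda_ridge: float = 0.0
    penalize_intercept: bool = True

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2:
            raise ValueError("B must be 2-D")
        if self.lambda_lasso < 0 or self.lambda_ridge < 0:
            raise ValueError("penalties must be nonnegative")
        if self.family not in (LINEAR, LOGISTIC):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def p(self) -> int:
        return self.B.shape[1]


@dataclass
class SlisemapSolution:
    """A fitted embedding + local-model pair and the loss it attains."""

    dataset: Dataset
    embedding: Embedding
    models: LocalModelBank
    loss: float
    seed: int | None = None
    optimizer_trace: list = field(default_factory=list)

    @property
    def Z(self) -> np.ndarray:
        return self.embedding.Z

    @property
    def B(self) -> np.ndarray:
        return self.models.B

    def recompute_loss(self) -> float:
        return slisemap_loss(
            self.embedding.Z,
            self.models.B,
            self.dataset.X,
            self.dataset.Y,
            family=self.models.family,
            lasso=self.models.lambda_lasso,
            ridge=self.models.lambda_ridge,
            squared_kernel=self.embedding.squared_kernel,
            penalize_intercept=self.models.penalize_intercept,
        )

    def local_loss_matrix(self) -> np.ndarray:
        """L[i, j] = loss of model i on item j."""
        return pairwise_local_loss(
            self.models.B, self.dataset.X, self.dataset.Y, self.models.family
        )

    def kernel(self) -> np.ndarray:
        return kernel_weights(self.embedding.Z, squared=self.embedding.squared_kernel)
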