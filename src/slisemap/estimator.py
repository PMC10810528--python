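"""Scikit-learn style estimators.

``Slisemap`` is the main entry point: ``fit(X, y)`` standardizes the data,
jointly optimises the 2-D embedding and the per-item local models, and
exposes the results as fitted attributes (``embedding_``,
``coefficients_``, ``loss_``).  ``FixedEmbeddingLocalModels`` fits the
local-model bank only, with the embedding frozen — the device used to give
unsupervised embeddings (PCA, t-SNE, UMAP, ...) comparable local
explanations.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .core import (
    Embedding,
    LocalModelBank,
    SlisemapSolution,
    slisemap_loss,
)
from .data import Dataset, LINEAR, LOGISTIC
from .optimizer import OptimizerConfig, fit_slisemap, fit_global_model
from scipy.optimize import minimize

__all__ = ["Slisemap", "FixedEmbeddingLocalModels"]

_FAMILY_ALIASES = {
    "linear": LINEAR,
    LINEAR: LINEAR,
    "logistic": LOGISTIC,
    LOGISTIC: LOGISTIC,
}


def _seed_from(random_state) -> int:
    if isinstance(random_state, numbers.Integral):
        return int(random_state) % (2**31)
    rs = check_random_state(random_state)
    return int(rs.randint(2**31))


def _feature_names(X):
    if hasattr(X, "columns"):
        return [str(c) for c in X.columns]
    return None


class Slisemap(BaseEstimator):
    """Supervised embedding with per-item interpretable local models.

    Minimises a softmax-kernel weighted sum of local-model losses over the
    embedding coordinates ``Z`` and coefficient matrix ``B`` jointly,
    under the constraint that the mean squared embedding norm equals
    ``radius**2``.  Items whose local models predict each other well end
    up close together, so the embedding groups items by *explanation*
    rather than by raw feature similarity.

    Parameters
    ----------
    n_components : int, default 2
        Embedding dimension d.
    radius : float, default 3.5
        Embedding radius r; the constraint is mean(|z_i|^2) = r^2.
    family : {"linear", "logistic"}, default "linear"
        Local-model family: linear regression with squared-error loss, or
        binary logistic regression with squared-Hellinger loss on soft
        labels.
    lasso, ridge : float, default 1e-4
        L1 / L2 penalties on all local-model coefficients.
    penalize_intercept : bool, default True
        Whether the intercept coefficients are included in the penalties.
    squared_kernel : bool, default False
        Use exp(-d^2) instead of exp(-d) in the softmax kernel.
    standardize : bool, default True
        Standardize features to zero mean / unit variance before fitting.
    standardize_target : {"auto", True, False}, default "auto"
        Standardize the target; "auto" means yes for regression, no for
        classification probabilities.
    init : {"pca", "random"}, default "pca"
        Embedding initialisation.
    escape : bool, default True
        Enable the greedy escape rounds after the first L-BFGS pass.
    max_rounds : int, default 50
        Maximum number of escape rounds.
    max_iter : int, default 200
        L-BFGS iteration cap per round.
    tol : float, default 1e-6
        Relative loss-change stopping criterion across rounds.
    random_state : int, RandomState or None
        Seed for initialisation and tie-breaking jitter.

    Attributes
    ----------
    embedding_ : (n, d) array
        Optimised coordinates.
    coefficients_ : (n, p) array
        Local-model coefficients, row i = model of item i (standardized
        units; the last column per output is the intercept).
    loss_ : float
        Final objective value.
    trace_ : list of (round, loss)
        Accepted-round loss sequence (non-increasing).
    solution_ : SlisemapSolution
        Full solution object consumed by the metric functions.

    Examples
    --------
    >>> from slisemap.datasets import generate_piecewise_1d
    >>> data = generate_piecewise_1d(n=80, seed=0)
    >>> sm = Slisemap(random_state=0).fit(data.X, data.y)
    >>> sm.embedding_.shape, sm.coefficients_.shape
    ((80, 2), (80, 2))
    """

    def __init__(
        self,
        n_components: int = 2,
        radius: float = 3.5,
        family: str = "linear",
        lasso: float = 1e-4,
        ridge: float = 1e-4,
        penalize_intercept: bool = True,
        squared_kernel: bool = False,
        standardize: bool = True,
        standardize_target="auto",
        init: str = "pca",
        escape: bool = True,
        max_rounds: int = 50,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state=None,
    ):
        self.n_components = n_components
        self.radius = radius
        self.family = family
        self.lasso = lasso
        self.ridge = ridge
        self.penalize_intercept = penalize_intercept
        self.squared_kernel = squared_kernel
        self.standardize = standardize
        self.standardize_target = standardize_target
        self.init = init
        self.escape = escape
        self.max_rounds = max_rounds
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build_dataset(self, X, y) -> Dataset:
        family = _FAMILY_ALIASES.get(self.family)
        if family is None:
            raise ValueError(f"unknown family {self.family!r}")
        names = _feature_names(X)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if family == LOGISTIC and y.ndim == 2 and y.shape[1] == 2:
            y = y[:, 1]  # positive-class probability
        if self.standardize:
            return Dataset.from_raw(
                X, y, feature_names=names, family=family,
                standardize_target=self.standardize_target,
            )
        Xm = np.hstack([X, np.ones((X.shape[0], 1))])
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        return Dataset(
            X=Xm, Y=y if y.ndim == 2 else y[:, None],
            feature_names=list(names) + ["intercept"],
            x_mean=np.zeros(X.shape[1]), x_scale=np.ones(X.shape[1]),
            family=family,
        )

    def fit(self, X, y):
        """Optimise the embedding and local models for (X, y)."""
        dataset = self._build_dataset(X, y)
        seed = _seed_from(self.random_state)
        config = OptimizerConfig(
            max_rounds=self.max_rounds,
            lbfgs_max_iter=self.max_iter,
            tolerance=self.tol,
            escape_enabled=self.escape,
            seed=seed,
            init_method=self.init,
        )
        solution = fit_slisemap(
            dataset,
            d=self.n_components,
            r=self.radius,
            lasso=self.lasso,
            ridge=self.ridge,
            squared_kernel=self.squared_kernel,
            penalize_intercept=self.penalize_intercept,
            config=config,
        )
        self.dataset_ = dataset
        self.solution_ = solution
        self.embedding_ = solution.Z
        self.coefficients_ = solution.B
        self.loss_ = solution.loss
        self.trace_ = solution.optimizer_trace
        self.n_features_in_ = dataset.m
        self.feature_names_in_ = np.asarray(dataset.feature_names[:-1], dtype=object)
        return self

    def fit_transform(self, X, y):
        """Fit and return the embedding coordinates."""
        return self.fit(X, y).embedding_

    def transform(self, X=None):
        """Embedding of the *training* items.

        The model has no out-of-sample extension; passing data other than
        the training features raises.
        """
        self._check_fitted()
        if X is not None:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            if Xa.shape != (self.dataset_.n, self.dataset_.m) or not np.allclose(
                Xa, self.dataset_.raw_features()
            ):
                raise ValueError("no out-of-sample extension: transform only the training data")
        return self.embedding_

    def predict(self, X=None):
        """Each item's own local-model prediction, on the raw target scale."""
        self._check_fitted()
        if X is not None:
            self.transform(X)  # validates it is the training data
        ds = self.dataset_
        L = self.solution_  # noqa: F841  (kept for symmetry)
        from .core import local_predict  # noqa: PLC0415

        preds = np.empty((ds.n, ds.o))
        for i in range(ds.n):
            out = local_predict(self.coefficients_[i], ds.X[i : i + 1], ds.family, ds.o)
            preds[i] = out[0, -ds.o:] if ds.family == LOGISTIC else out[0]
        if ds.y_mean is not None:
            preds = preds * ds.y_scale + ds.y_mean
        return preds[:, 0] if ds.o == 1 else preds

    def _check_fitted(self):
        if not hasattr(self, "solution_"):
            raise AttributeError("this Slisemap instance is not fitted yet")


class FixedEmbeddingLocalModels(BaseEstimator):
    """Local models fitted under a frozen, externally supplied embedding.

    Minimises the same kernel-weighted objective, but only over the
    coefficient matrix ``B``; the embedding (from PCA, t-SNE, UMAP, a CSV
    of coordinates, ...) stays fixed.  This makes the explanation-quality
    metrics comparable across embedding methods.

    Parameters are as in :class:`Slisemap` where they overlap; ``embedding``
    is the (n, d) coordinate matrix, radius-projected before use so kernel
    bandwidths are comparable with fitted solutions.
    """

    def __init__(
        self,
        embedding=None,
        radius: float = 3.5,
        family: str = "linear",
        lasso: float = 1e-4,
        ridge: float = 1e-4,
        penalize_intercept: bool = True,
        squared_kernel: bool = False,
        standardize: bool = True,
        standardize_target="auto",
        max_iter: int = 200,
        project_embedding: bool = True,
    ):
        self.embedding = embedding
        self.radius = radius
        self.family = family
        self.lasso = lasso
        self.ridge = ridge
        self.penalize_intercept = penalize_intercept
        self.squared_kernel = squared_kernel
        self.standardize = standardize
        self.standardize_target = standardize_target
        self.max_iter = max_iter
        self.project_embedding = project_embedding

    def fit(self, X, y):
        if self.embedding is None:
            raise ValueError("an embedding matrix must be supplied")
        dataset = Slisemap(
            family=self.family,
            standardize=self.standardize,
            standardize_target=self.standardize_target,
        )._build_dataset(X, y)
        bank = fit_local_models_on_embedding(
            np.asarray(self.embedding, dtype=float),
            dataset,
            lasso=self.lasso,
            ridge=self.ridge,
            radius=self.radius,
            penalize_intercept=self.penalize_intercept,
            squared_kernel=self.squared_kernel,
            max_iter=self.max_iter,
            project_embedding=self.project_embedding,
        )
        Z = np.asarray(self.embedding, dtype=float)
        if self.project_embedding:
            from .core import project_to_radius  # noqa: PLC0415

            Z = project_to_radius(Z, self.radius)
        loss = slisemap_loss(
            Z, bank.B, dataset.X, dataset.Y, family=dataset.family,
            lasso=self.lasso, ridge=self.ridge,
            squared_kernel=self.squared_kernel,
            penalize_intercept=self.penalize_intercept,
        )
        self.dataset_ = dataset
        self.coefficients_ = bank.B
        self.loss_ = loss
        self.solution_ = SlisemapSolution(
            dataset=dataset,
            embedding=Embedding(Z, d=Z.shape[1], r=self.radius,
                                squared_kernel=self.squared_kernel),
            models=bank,
            loss=loss,
        )
        return self


def fit_local_models_on_embedding(
    Z_fixed: np.ndarray,
    dataset: Dataset,
    *,
    lasso: float = 1e-4,
    ridge: float = 1e-4,
    radius: float = 3.5,
    penalize_intercept: bool = True,
    squared_kernel: bool = False,
    max_iter: int = 200,
    project_embedding: bool = True,
) -> LocalModelBank:
    """Minimise the objective over ``B`` with the embedding frozen.

    A pure-ridge=0 linear fit can be unidentifiable when the weighted
    design is rank deficient, so a tiny ridge floor is applied (with a
    warning) when ``ridge == 0``.
    """
    import warnings

    from .core import _pairwise_loss_and_bgrad, _intercept_mask, kernel_weights, project_to_radius

    if ridge == 0.0:
        warnings.warn("ridge floor 1e-8 applied to keep the frozen-embedding fit identifiable")
        ridge = 1e-8
    Z = np.asarray(Z_fixed, dtype=float)
    if Z.shape[0] != dataset.n:
        raise ValueError("embedding rows do not match the dataset")
    if project_embedding:
        Z = project_to_radius(Z, radius)
    W = kernel_weights(Z, squared=squared_kernel)
    n, p = dataset.n, dataset.p
    X, Y, family = dataset.X, dataset.Y, dataset.family
    mask = np.ones(p, dtype=bool)
    if not penalize_intercept:
        mask = ~_intercept_mask(p, X.shape[1], family)

    def fun(b):
        B = b.reshape(n, p)
        L, gB = _pairwise_loss_and_bgrad(B, X, Y, family, W)
        pen = lasso * np.abs(B[:, mask]).sum() + ridge * (B[:, mask] ** 2).sum()
        g = gB
        g[:, mask] += lasso * np.sign(B[:, mask]) + 2.0 * ridge * B[:, mask]
        return float((W * L).sum() + pen), g.ravel()

    b0 = np.tile(fit_global_model(dataset, lasso=lasso, ridge=ridge,
                                  penalize_intercept=penalize_intercept), (n, 1))
    res = minimize(fun, b0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "maxls": 50})
    return LocalModelBank(
        res.x.reshape(n, p), family=family, lambda_lasso=lasso,
        lambda_ridge=ridge, penalize_intercept=penalize_intercept,
    )
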