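"""Joint optimisation of the embedding and the local models.

The objective is minimised with L-BFGS over a radius-normalised
parametrisation of the embedding: internally the optimiser works with free
coordinates ``V`` and evaluates the loss at ``Z = r * V / rms(V)``, so the
mean-squared-radius constraint holds exactly at every function evaluation
(the unconstrained loss has no finite minimiser — spreading the embedding
out makes the softmax kernel degenerate — so the constraint must be active
throughout, not just at the end).

Quasi-Newton descent alone tends to get stuck in local optima where an
item sits in the "wrong" part of the embedding: moving it there is uphill
for every small step even though the models around another position
predict it better.  The greedy escape heuristic handles this by proposing,
for each item, a jump to the existing embedding position whose local
neighbourhood predicts the item best, refitting with L-BFGS, and keeping
the jump only if the total loss strictly decreased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.decomposition import PCA

from .core import (
    Embedding,
    LocalModelBank,
    SlisemapSolution,
    kernel_weights,
    pairwise_local_loss,
    project_to_radius,
    slisemap_loss_grad,
)
from .data import Dataset, LINEAR, LOGISTIC

__all__ = ["OptimizerConfig", "initialize", "fit_slisemap", "escape_step", "fit_global_model", "subsample"]


@dataclass
class OptimizerConfig:
    """Knobs of the alternating L-BFGS / escape loop."""

    max_rounds: int = 50
    lbfgs_max_iter: int = 200
    tolerance: float = 1e-6
    escape_enabled: bool = True
    seed: int = 0
    init_method: str = "pca"
    escape_patience: int = 4  # consecutive non-improving escape rounds tolerated

    def __post_init__(self):
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.init_method not in ("pca", "random"):
            raise ValueError("init_method must be 'pca' or 'random'")


# ----------------------------------------------------------------------
def fit_global_model(
    dataset: Dataset,
    *,
    lasso: float = 0.0,
    ridge: float = 0.0,
    penalize_intercept: bool = True,
    max_iter: int = 200,
) -> np.ndarray:
    """One model for all items, fitted with uniform weights.

    Used for initialising the local-model bank and as the reference model
    behind the default coverage tolerance.  Returns a length-p vector.
    """
    n = dataset.n
    p = dataset.p
    X, Y = dataset.X, dataset.Y
    family = dataset.family

    W = np.full((1, n), 1.0 / n)

    def fun(b):
        B = b[None, :]
        # reuse the joint machinery with a single "model row"
        from .core import _pairwise_loss_and_bgrad, _intercept_mask  # noqa: PLC0415

        L, gB = _pairwise_loss_and_bgrad(B, X, Y, family, W)
        mask = np.ones(p, dtype=bool)
        if not penalize_intercept:
            mask = ~_intercept_mask(p, X.shape[1], family)
        pen = lasso * np.abs(B[:, mask]).sum() + ridge * (B[:, mask] ** 2).sum()
        g = gB[0].copy()
        g[mask] += lasso * np.sign(b[mask]) + 2.0 * ridge * b[mask]
        return float((W * L).sum() + pen), g

    res = minimize(fun, np.zeros(p), jac=True, method="L-BFGS-B", options={"maxiter": max_iter})
    return res.x


def initialize(dataset: Dataset, config: OptimizerConfig, *, d: int = 2, r: float = 3.5,
               lasso: float = 0.0, ridge: float = 0.0, penalize_intercept: bool = True):
    """Initial embedding (PCA or seeded Gaussian, radius-projected) and
    global-fit coefficient bank."""
    Xf = dataset.X[:, :-1]  # drop the intercept column
    if np.allclose(Xf.std(axis=0), 0):
        raise ValueError("degenerate features: zero variance everywhere")
    rng = np.random.default_rng(config.seed)
    if config.init_method == "pca":
        k = min(d, Xf.shape[1], dataset.n)
        Z0 = PCA(n_components=k, random_state=config.seed).fit_transform(Xf)
        if k < d:  # pad with tiny seeded noise so Z0 is (n, d)
            pad = rng.normal(scale=1e-2, size=(dataset.n, d - k))
            Z0 = np.hstack([Z0, pad])
    else:
        Z0 = rng.normal(size=(dataset.n, d))
    Z0 = project_to_radius(Z0, r)
    b0 = fit_global_model(
        dataset, lasso=lasso, ridge=ridge, penalize_intercept=penalize_intercept
    )
    B0 = np.tile(b0, (dataset.n, 1))
    return Z0, B0


# ----------------------------------------------------------------------
def _make_objective(dataset, d, r, lasso, ridge, squared_kernel, penalize_intercept):
    n, p = dataset.n, dataset.p
    X, Y, family = dataset.X, dataset.Y, dataset.family

    def unpack(theta):
        V = theta[: n * d].reshape(n, d)
        B = theta[n * d :].reshape(n, p)
        return V, B

    def fun(theta):
        V, B = unpack(theta)
        ssq = (V**2).sum()
        rms = np.sqrt(ssq / n)
        c = r / rms
        Z = V * c
        loss, gZ, gB = slisemap_loss_grad(
            Z, B, X, Y, family=family, lasso=lasso, ridge=ridge,
            squared_kernel=squared_kernel, penalize_intercept=penalize_intercept,
        )
        # chain rule through the radius normalisation Z = (r/rms(V)) * V
        gV = c * gZ - (r / (n * rms**3)) * float((gZ * V).sum()) * V
        return loss, np.concatenate([gV.ravel(), gB.ravel()])

    return fun, unpack


def _lbfgs(fun, theta0, max_iter):
    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "maxls": 50})
    if not np.isfinite(res.fun):
        raise FloatingPointError("optimisation produced a non-finite loss")
    return res.x, float(res.fun)


def _propose_relocations(Z, B, dataset, squared_kernel):
    """Greedy candidate step: move each item to the existing position whose
    neighbourhood predicts it best (strict improvements only)."""
    W = kernel_weights(Z, squared=squared_kernel)
    L = pairwise_local_loss(B, dataset.X, dataset.Y, dataset.family)
    # proxy[j, i] = weighted loss of the models around z_j on item i
    proxy = W @ L
    best = np.argmin(proxy, axis=0)
    current = np.diagonal(proxy)
    improve = proxy[best, np.arange(len(best))] < current - 1e-12
    moved = np.flatnonzero(improve)
    Z2, B2 = Z.copy(), B.copy()
    Z2[moved] = Z[best[moved]]
    B2[moved] = B[best[moved]]
    return Z2, B2, moved


def _escape_candidate(solution: SlisemapSolution, *, lbfgs_max_iter: int = 200,
                      jitter_rng: np.random.Generator | None = None):
    """Relocate-and-refit candidate, returned whether or not it improves
    (``None`` when no relocation is proposed)."""
    ds = solution.dataset
    emb, bank = solution.embedding, solution.models
    Z, B = emb.Z, bank.B
    Z2, B2, moved = _propose_relocations(Z, B, ds, emb.squared_kernel)
    if moved.size == 0:
        return None
    if jitter_rng is not None:  # break exact coincidences so L-BFGS can separate
        Z2[moved] += jitter_rng.normal(scale=1e-3, size=(moved.size, Z.shape[1]))
    Z2 = project_to_radius(Z2, emb.r)
    fun, unpack = _make_objective(
        ds, emb.d, emb.r, bank.lambda_lasso, bank.lambda_ridge,
        emb.squared_kernel, bank.penalize_intercept,
    )
    theta0 = np.concatenate([Z2.ravel(), B2.ravel()])
    theta, loss = _lbfgs(fun, theta0, lbfgs_max_iter)
    V, Bn = unpack(theta)
    Zn = project_to_radius(V, emb.r)
    return SlisemapSolution(
        dataset=ds,
        embedding=Embedding(Zn, d=emb.d, r=emb.r, squared_kernel=emb.squared_kernel),
        models=LocalModelBank(Bn, family=bank.family, lambda_lasso=bank.lambda_lasso,
                              lambda_ridge=bank.lambda_ridge,
                              penalize_intercept=bank.penalize_intercept),
        loss=loss,
        seed=solution.seed,
        optimizer_trace=list(solution.optimizer_trace),
    )


def escape_step(solution: SlisemapSolution, *, lbfgs_max_iter: int = 200,
                jitter_rng: np.random.Generator | None = None) -> SlisemapSolution:
    """One greedy escape round: relocate, refit, keep only if the total
    loss strictly decreases; otherwise the solution is returned unchanged."""
    cand = _escape_candidate(solution, lbfgs_max_iter=lbfgs_max_iter,
                             jitter_rng=jitter_rng)
    if cand is None or cand.loss >= solution.loss:
        return solution
    return cand


def fit_slisemap(
    dataset: Dataset,
    *,
    d: int = 2,
    r: float = 3.5,
    lasso: float = 1e-4,
    ridge: float = 1e-4,
    squared_kernel: bool = False,
    penalize_intercept: bool = True,
    config: OptimizerConfig | None = None,
) -> SlisemapSolution:
    """Fit the full solution: initialise, L-BFGS, then escape rounds."""
    if config is None:
        config = OptimizerConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    Z0, B0 = initialize(dataset, config, d=d, r=r, lasso=lasso, ridge=ridge,
                        penalize_intercept=penalize_intercept)
    fun, unpack = _make_objective(dataset, d, r, lasso, ridge,
                                  squared_kernel, penalize_intercept)
    theta0 = np.concatenate([Z0.ravel(), B0.ravel()])
    theta, loss = _lbfgs(fun, theta0, config.lbfgs_max_iter)
    V, B = unpack(theta)
    Z = project_to_radius(V, r)
    trace = [(0, loss)]
    solution = SlisemapSolution(
        dataset=dataset,
        embedding=Embedding(Z, d=d, r=r, squared_kernel=squared_kernel),
        models=LocalModelBank(B, family=dataset.family, lambda_lasso=lasso,
                              lambda_ridge=ridge, penalize_intercept=penalize_intercept),
        loss=loss,
        seed=config.seed,
        optimizer_trace=trace,
    )
    if config.escape_enabled:
        # explore with patience: rounds continue from the latest candidate
        # (even a worse one) so consecutive relocations can cross loss
        # barriers; only strict improvements on the best-so-far are
        # accepted into the solution and its (non-increasing) trace
        best = solution
        current = solution
        no_improve = 0
        for rnd in range(1, config.max_rounds + 1):
            cand = _escape_candidate(current, lbfgs_max_iter=config.lbfgs_max_iter,
                                     jitter_rng=rng)
            if cand is None:
                break
            current = cand
            gain = best.loss - cand.loss
            if gain > 0:
                best = cand
                best.optimizer_trace = best.optimizer_trace + [(rnd, cand.loss)]
            if gain < config.tolerance * max(abs(best.loss), 1e-12):
                no_improve += 1
                if no_improve >= config.escape_patience:
                    break
            else:
                no_improve = 0
        solution = best
    return solution


# ----------------------------------------------------------------------
def subsample(dataset: Dataset, n_max: int = 5000, seed: int = 0) -> Dataset:
    """Seeded uniform subsample for large datasets (the objective scales
    quadratically in n); no out-of-sample extension is provided."""
    if dataset.n <= n_max:
        return dataset
    rng = np.random.default_rng(seed)
    idx = rng.choice(dataset.n, size=n_max, replace=False)
    return dataset.subset(np.sort(idx))
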