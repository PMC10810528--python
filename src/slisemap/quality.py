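"""Explanation-quality metrics: local loss, NN local loss, coverage.

These answer "how good are the explanations themselves": does each local
model fit its own item (local loss), does it also fit the item's nearest
neighbours (NN local loss), and what fraction of items does it generalise
to within a loss tolerance (coverage, NN coverage)?  Computed for any
(embedding, local-model-bank) pair, so supervised solutions can be
compared against local models trained on a frozen unsupervised embedding
(PCA, t-SNE, UMAP) or against explanation methods without an embedding,
in which case neighbours live in the original data space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import SlisemapSolution
from .optimizer import fit_global_model

__all__ = [
    "QualityReport",
    "local_loss",
    "nn_local_loss",
    "coverage",
    "default_tolerance",
    "quality_report",
]


@dataclass
class QualityReport:
    local_loss: float
    nn_local_loss: float
    coverage: float
    nn_coverage: float
    tolerance_used: float
    k_neighbours: int
    neighbour_space: str

    def __post_init__(self):
        if not (0 <= self.coverage <= 1 and 0 <= self.nn_coverage <= 1):
            raise ValueError("coverages must lie in [0, 1]")
        if self.k_neighbours < 1:
            raise ValueError("k_neighbours must be >= 1")


def _neighbour_index(solution: SlisemapSolution, k: int, space: str) -> np.ndarray:
    """Indices of the k nearest neighbours of each item (self excluded);
    Euclidean distance, ties broken by index via stable argsort."""
    if space == "embedding":
        P = solution.Z
    elif space == "data":
        P = solution.dataset.X[:, :-1]
    else:
        raise ValueError("neighbour_space must be 'embedding' or 'data'")
    n = P.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of items")
    D = cdist(P, P)
    np.fill_diagonal(D, np.inf)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def local_loss(solution: SlisemapSolution) -> float:
    """Mean loss of every local model on its own item."""
    L = solution.local_loss_matrix()
    return float(np.mean(np.diagonal(L)))


def nn_local_loss(solution: SlisemapSolution, k: int = 20,
                  neighbour_space: str = "embedding") -> float:
    """Mean loss of each local model on its item's k nearest neighbours."""
    L = solution.local_loss_matrix()
    nn = _neighbour_index(solution, k, neighbour_space)
    rows = np.arange(L.shape[0])[:, None]
    return float(L[rows, nn].mean())


def default_tolerance(solution: SlisemapSolution, quantile: float = 0.3) -> float:
    """Loss quantile of a single uniformly weighted global model.

    A scale-free reference: a local model "covers" an item when it beats
    the bulk of what one global model achieves.
    """
    ds = solution.dataset
    b = fit_global_model(ds, lasso=solution.models.lambda_lasso,
                         ridge=solution.models.lambda_ridge,
                         penalize_intercept=solution.models.penalize_intercept)
    from .core import pairwise_local_loss  # noqa: PLC0415

    losses = pairwise_local_loss(b[None, :], ds.X, ds.Y, ds.family)[0]
    return float(np.quantile(losses, quantile))


def coverage(solution: SlisemapSolution, tolerance: float | None = None,
             k: int = 20, neighbour_space: str = "embedding"):
    """(coverage, nn_coverage): fraction of items / of k nearest
    neighbours each local model predicts within ``tolerance``."""
    if tolerance is None:
        tolerance = default_tolerance(solution)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    L = solution.local_loss_matrix()
    cov = float((L <= tolerance).mean())
    nn = _neighbour_index(solution, k, neighbour_space)
    rows = np.arange(L.shape[0])[:, None]
    nn_cov = float((L[rows, nn] <= tolerance).mean())
    return cov, nn_cov


def quality_report(solution: SlisemapSolution, *, k: int = 20,
                   tolerance: float | None = None,
                   neighbour_space: str = "embedding") -> QualityReport:
    """All four explanation-quality metrics for one solution."""
    if tolerance is None:
        tolerance = default_tolerance(solution)
    cov, nn_cov = coverage(solution, tolerance, k, neighbour_space)
    return QualityReport(
        local_loss=local_loss(solution),
        nn_local_loss=nn_local_loss(solution, k, neighbour_space),
        coverage=cov,
        nn_coverage=nn_cov,
        tolerance_used=float(tolerance),
        k_neighbours=k,
        neighbour_space=neighbour_space,
    )
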