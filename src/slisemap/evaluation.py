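"""Stability measures for fitted solutions and the resampling protocol.

Three measures, each answering a different "is this real?" question:

* **permutation loss** — ratio of the optimised loss on the true targets
  to the loss re-optimised after randomly permuting the targets; values
  below 1 mean the solution captured a genuine feature-target relation
  (a sanity check against visualising noise).
* **local model stability** — fit two solutions on resampled data and
  match their local models one-to-one with the Hungarian algorithm;
  ``1 - (matched cost) / (mean pairwise cost)`` is near 1 when the two
  runs found the same population of explanations.
* **neighbourhood stability** — fit two solutions on samples sharing 50%
  of the items and compare, for each shared item, its radius-1 embedding
  neighbourhood across the runs via Jaccard similarity.

The protocol repeats each measure over seeded resamples at a range of
sample sizes and also computes a permuted-target baseline for the
stability measures, mirroring how one decides whether a visualisation of
a real dataset can be trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.base import clone

__all__ = [
    "StabilityReport",
    "permutation_loss",
    "local_model_stability",
    "neighbourhood_stability",
    "stability_protocol",
]


# ----------------------------------------------------------------------
def permutation_loss(estimator, X, y, *, n_permutations: int = 1, random_state: int = 0):
    """Mean of L / L_permuted over seeded target permutations.

    Both fits run from scratch with the estimator's own settings; only the
    permutation of ``y`` differs.  Values < 1 indicate captured signal.
    """
    y = np.asarray(y)
    est = clone(estimator).set_params(random_state=random_state)
    est.fit(X, y)
    L = est.loss_
    seeds = np.random.SeedSequence(random_state).generate_state(n_permutations)
    ratios = []
    for s in seeds:
        rng = np.random.default_rng(int(s))
        yp = y[rng.permutation(len(y))]
        ep = clone(estimator).set_params(random_state=int(s) % (2**31))
        ep.fit(X, yp)
        if ep.loss_ == 0:
            raise ZeroDivisionError("permuted-target loss is zero (degenerate data)")
        ratios.append(L / ep.loss_)
    out = float(np.mean(ratios))
    return out if n_permutations > 1 else out


def local_model_stability(B1: np.ndarray, B2: np.ndarray) -> float:
    """Hungarian-matched similarity of two local-model populations.

    ``1 - min_pi sum_i D(B1_i, B2_pi(i)) / (sum_ij D(B1_i, B2_j) / n)``
    with Euclidean distances between coefficient rows.  Equals 1 when a
    perfect matching of identical models exists; by convention also 1 when
    all models in both banks coincide (zero normalizer).
    """
    B1 = np.atleast_2d(np.asarray(B1, dtype=float))
    B2 = np.atleast_2d(np.asarray(B2, dtype=float))
    if B1.shape != B2.shape:
        raise ValueError("coefficient matrices must have equal shapes")
    n = B1.shape[0]
    D = cdist(B1, B2)
    normalizer = D.sum() / n
    if normalizer == 0.0:
        return 1.0
    rows, cols = linear_sum_assignment(D)
    cost = D[rows, cols].sum()
    return 1.0 - cost / normalizer


def neighbourhood_stability(
    Z1: np.ndarray,
    Z2: np.ndarray,
    shared1,
    shared2,
    radius: float = 1.0,
) -> float:
    """Mean Jaccard overlap of radius-limited embedding neighbourhoods.

    ``shared1``/``shared2`` index the same shared items (in order) in the
    two embeddings; neighbourhoods are restricted to the shared set.  The
    result is in (0, 1]: every item belongs to both of its own
    neighbourhoods, so no per-item Jaccard can be 0.
    """
    shared1 = np.asarray(shared1)
    shared2 = np.asarray(shared2)
    if shared1.size == 0:
        raise ValueError("the shared set is empty")
    if shared1.size != shared2.size:
        raise ValueError("shared index lists must have equal length")
    S1 = np.asarray(Z1, dtype=float)[shared1]
    S2 = np.asarray(Z2, dtype=float)[shared2]
    A = cdist(S1, S1) <= radius
    Bm = cdist(S2, S2) <= radius
    inter = (A & Bm).sum(axis=1)
    union = (A | Bm).sum(axis=1)
    return float(np.mean(inter / union))


# ----------------------------------------------------------------------
@dataclass
class StabilityReport:
    """Stability measures at one sample size, averaged over repeats."""

    size: int
    n_repeats: int
    m_permutation: float | None = None
    m_models: float | None = None
    m_neighbourhood: float | None = None
    sd_permutation: float | None = None
    sd_models: float | None = None
    sd_neighbourhood: float | None = None
    baseline_models: float | None = None
    baseline_neighbourhood: float | None = None
    per_repeat: dict = field(default_factory=dict)
    baseline_per_repeat: dict = field(default_factory=dict)


def _draw_disjoint(rng, pool: int, size: int):
    """Two size-``size`` samples, disjoint when the pool allows, otherwise
    overlapping independent draws."""
    if 2 * size <= pool:
        perm = rng.permutation(pool)
        return perm[:size], perm[size : 2 * size]
    a = rng.choice(pool, size=size, replace=False)
    b = rng.choice(pool, size=size, replace=False)
    return a, b


def _draw_half_shared(rng, pool: int, size: int):
    """Two samples of ``size`` sharing exactly half their items."""
    if size % 2:
        raise ValueError("the 50%-shared scheme needs an even sample size")
    half = size // 2
    if size + half <= pool:
        perm = rng.permutation(pool)
        shared = perm[:half]
        a = np.concatenate([shared, perm[half : half + half]])
        b = np.concatenate([shared, perm[2 * half : 3 * half]])
    else:
        shared = rng.choice(pool, size=half, replace=False)
        rest = np.setdiff1d(np.arange(pool), shared)
        a = np.concatenate([shared, rng.choice(rest, size=half, replace=False)])
        b = np.concatenate([shared, rng.choice(rest, size=half, replace=False)])
    return a, b, np.arange(half)


def stability_protocol(
    estimator,
    X,
    y,
    sizes,
    *,
    n_repeats: int = 10,
    random_state: int = 0,
    metrics=("permutation", "models", "neighbourhood"),
    neighbourhood_radius: float = 1.0,
):
    """Run the resampling stability protocol; one report per sample size.

    For each size and repeat: (a) permutation loss on one subsample;
    (b) local-model stability between fits on two disjoint subsamples,
    with a baseline where the second fit sees permuted targets;
    (c) neighbourhood stability between fits on two subsamples sharing
    exactly 50% of items, with the same kind of baseline.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    pool = X.shape[0]
    reports = {}
    for size in sizes:
        if size > pool:
            raise ValueError(f"requested size {size} exceeds the {pool} items available")
        per = {k: [] for k in metrics}
        base = {k: [] for k in metrics if k != "permutation"}
        for rep in range(n_repeats):
            ss = np.random.SeedSequence(random_state, spawn_key=(int(size), rep))
            seeds = ss.generate_state(8).astype(np.int64) % (2**31)
            rng = np.random.default_rng(seeds[0])
            if "permutation" in metrics:
                idx = rng.choice(pool, size=size, replace=False)
                per["permutation"].append(
                    permutation_loss(estimator, X[idx], y[idx],
                                     random_state=int(seeds[1]))
                )
            if "models" in metrics:
                a, b = _draw_disjoint(rng, pool, size)
                e1 = clone(estimator).set_params(random_state=int(seeds[2])).fit(X[a], y[a])
                e2 = clone(estimator).set_params(random_state=int(seeds[3])).fit(X[b], y[b])
                per["models"].append(local_model_stability(e1.coefficients_, e2.coefficients_))
                yb = np.asarray(y)[b]
                yb = yb[np.random.default_rng(seeds[4]).permutation(size)]
                e2p = clone(estimator).set_params(random_state=int(seeds[4])).fit(X[b], yb)
                base["models"].append(local_model_stability(e1.coefficients_, e2p.coefficients_))
            if "neighbourhood" in metrics:
                size_even = size - (size % 2)
                a, b, shared = _draw_half_shared(rng, pool, size_even)
                e1 = clone(estimator).set_params(random_state=int(seeds[5])).fit(X[a], y[a])
                e2 = clone(estimator).set_params(random_state=int(seeds[6])).fit(X[b], y[b])
                per["neighbourhood"].append(
                    neighbourhood_stability(e1.embedding_, e2.embedding_,
                                            shared, shared, radius=neighbourhood_radius)
                )
                yb = np.asarray(y)[b]
                yb = yb[np.random.default_rng(seeds[7]).permutation(size_even)]
                e2p = clone(estimator).set_params(random_state=int(seeds[7])).fit(X[b], yb)
                base["neighbourhood"].append(
                    neighbourhood_stability(e1.embedding_, e2p.embedding_,
                                            shared, shared, radius=neighbourhood_radius)
                )
        rep_out = StabilityReport(size=int(size), n_repeats=n_repeats,
                                  per_repeat=per, baseline_per_repeat=base)
        if "permutation" in metrics:
            rep_out.m_permutation = float(np.mean(per["permutation"]))
            rep_out.sd_permutation = float(np.std(per["permutation"]))
        if "models" in metrics:
            rep_out.m_models = float(np.mean(per["models"]))
            rep_out.sd_models = float(np.std(per["models"]))
            rep_out.baseline_models = float(np.mean(base["models"]))
        if "neighbourhood" in metrics:
            rep_out.m_neighbourhood = float(np.mean(per["neighbourhood"]))
            rep_out.sd_neighbourhood = float(np.std(per["neighbourhood"]))
            rep_out.baseline_neighbourhood = float(np.mean(base["neighbourhood"]))
        reports[int(size)] = rep_out
    return reports
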