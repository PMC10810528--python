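"""Independent oracles used by the tests.

Everything here is written from the mathematical definitions with plain
Python loops, deliberately sharing no code with the package internals, so
agreement is evidence and not tautology.
"""

import itertools
import math

import numpy as np


def _euclid(a, b):
    return math.sqrt(sum((float(x) - float(y)) ** 2 for x, y in zip(a, b)))


def brute_force_loss(Z, B, X, Y, family, lasso=0.0, ridge=0.0):
    """Triple-loop evaluation of the kernel-weighted objective."""
    n = len(Z)
    m1 = len(X[0])
    o = len(Y[0])
    total = 0.0
    for i in range(n):
        den = sum(math.exp(-_euclid(Z[i], Z[k])) for k in range(n))
        for j in range(n):
            w = math.exp(-_euclid(Z[i], Z[j])) / den
            if family == "linear_regression":
                l = 0.0
                for c in range(o):
                    pred = sum(X[j][f] * B[i][c * m1 + f] for f in range(m1))
                    l += (pred - Y[j][c]) ** 2
            else:
                t = sum(X[j][f] * B[i][f] for f in range(m1))
                p = 1.0 / (1.0 + math.exp(-t))
                q = Y[j][0]
                l = (math.sqrt(p) - math.sqrt(q)) ** 2 + (
                    math.sqrt(1 - p) - math.sqrt(1 - q)
                ) ** 2
            total += w * l
    for i in range(n):
        for j in range(len(B[0])):
            total += lasso * abs(B[i][j]) + ridge * B[i][j] ** 2
    return total


def brute_force_matching_cost(D):
    """Minimum assignment cost by exhaustive permutation enumeration."""
    n = D.shape[0]
    best = math.inf
    for perm in itertools.permutations(range(n)):
        cost = sum(D[i, perm[i]] for i in range(n))
        best = min(best, cost)
    return best


def finite_difference_grad(f, A, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    A = np.asarray(A, dtype=float)
    g = np.zeros_like(A)
    for idx in np.ndindex(A.shape):
        A[idx] += eps
        fp = f(A)
        A[idx] -= 2 * eps
        fm = f(A)
        A[idx] += eps
        g[idx] = (fp - fm) / (2 * eps)
    return g


def random_instance(seed, family="linear_regression", n=None, o=1):
    """Small random problem instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(2, 6))
    m = int(rng.integers(1, 4))
    d = 2
    X = np.hstack([rng.normal(size=(n, m)), np.ones((n, 1))])
    if family == "linear_regression":
        Y = rng.normal(size=(n, o))
        p = (m + 1) * o
    else:
        Y = rng.uniform(0.05, 0.95, size=(n, 1))
        p = m + 1
    Z = rng.normal(size=(n, d))
    B = rng.normal(size=(n, p)) * 0.5 + 0.1
    return Z, B, X, Y
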