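"""Explanation-quality metrics and frozen-embedding local models."""

import numpy as np
import pytest

from slisemap.core import Embedding, LocalModelBank, SlisemapSolution, slisemap_loss
from slisemap.data import Dataset
from slisemap.estimator import fit_local_models_on_embedding
from slisemap.optimizer import fit_global_model
from slisemap.quality import coverage, local_loss, nn_local_loss, quality_report


def _manual_solution(X_feat, y, Z, B, **bank_kw):
    """Assemble a solution object from explicit matrices (already scaled)."""
    n = len(y)
    X = np.hstack([np.asarray(X_feat, float), np.ones((n, 1))])
    ds = Dataset(X=X, Y=np.asarray(y, float)[:, None],
                 feature_names=[f"x{i}" for i in range(X.shape[1] - 1)] + ["intercept"],
                 x_mean=np.zeros(X.shape[1] - 1), x_scale=np.ones(X.shape[1] - 1))
    emb = Embedding(np.asarray(Z, float), d=Z.shape[1], r=3.5)
    bank = LocalModelBank(np.asarray(B, float), **bank_kw)
    loss = slisemap_loss(emb.Z, bank.B, ds.X, ds.Y)
    return SlisemapSolution(dataset=ds, embedding=emb, models=bank, loss=loss)


class TestLocalLoss:
    def test_interpolating_models_score_zero(self, rng):
        x = rng.normal(size=(4, 1))
        y = rng.normal(size=4)
        B = np.column_stack([np.zeros(4), y])  # slope 0, intercept y_i
        sol = _manual_solution(x, y, rng.normal(size=(4, 2)), B)
        assert local_loss(sol) == pytest.approx(0.0)

    def test_matches_direct_loop(self, rng):
        n = 5
        x = rng.normal(size=(n, 1))
        y = rng.normal(size=n)
        B = rng.normal(size=(n, 2))
        sol = _manual_solution(x, y, rng.normal(size=(n, 2)), B)
        expected = np.mean([
            (B[i, 0] * x[i, 0] + B[i, 1] - y[i]) ** 2 for i in range(n)
        ])
        assert local_loss(sol) == pytest.approx(expected)


class TestNNLocalLoss:
    def test_three_point_hand_instance(self):
        # Z places 0-1 adjacent and 2 far away; with k=1 each item is
        # scored on its single nearest neighbour
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 4.0])
        B = np.array([[1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        Z = np.array([[0.0, 0.0], [0.5, 0.0], [5.0, 0.0]])
        sol = _manual_solution(x, y, Z, B)
        # nn(0)=1, nn(1)=0, nn(2)=1
        expected = np.mean([
            (1.0 * 1.0 + 0.0 - 1.0) ** 2,
            (1.0 * 0.0 + 0.0 - 0.0) ** 2,
            (2.0 * 1.0 + 0.0 - 1.0) ** 2,
        ])
        assert nn_local_loss(sol, k=1) == pytest.approx(expected)

    def test_identical_items_make_nn_equal_local(self, rng):
        x = np.ones((5, 1)) * 2.0
        y = np.full(5, 3.0)
        B = rng.normal(size=(5, 2))
        sol = _manual_solution(x, y, rng.normal(size=(5, 2)), B)
        assert nn_local_loss(sol, k=2) == pytest.approx(local_loss(sol))

    def test_data_space_neighbours_supported(self, rng):
        x = rng.normal(size=(6, 1))
        sol = _manual_solution(x, rng.normal(size=6), rng.normal(size=(6, 2)),
                               rng.normal(size=(6, 2)))
        v = nn_local_loss(sol, k=2, neighbour_space="data")
        assert np.isfinite(v) and v >= 0

    def test_k_must_be_smaller_than_n(self, rng):
        sol = _manual_solution(rng.normal(size=(3, 1)), rng.normal(size=3),
                               rng.normal(size=(3, 2)), rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            nn_local_loss(sol, k=3)


class TestCoverage:
    def test_global_exact_model_covers_everything(self):
        x = np.linspace(-1, 1, 6)[:, None]
        y = 2 * x[:, 0] + 1
        B = np.tile([2.0, 1.0], (6, 1))
        sol = _manual_solution(x, y, np.random.default_rng(0).normal(size=(6, 2)), B)
        cov, nn_cov = coverage(sol, tolerance=0.1, k=2)
        assert cov == 1.0 and nn_cov == 1.0

    def test_tiny_tolerance_leaves_only_self_coverage(self, rng):
        x = rng.normal(size=(5, 1))
        y = np.arange(5.0)  # distinct targets
        B = np.column_stack([np.zeros(5), y])  # interpolate own item only
        sol = _manual_solution(x, y, rng.normal(size=(5, 2)), B)
        cov, _ = coverage(sol, tolerance=1e-12, k=2)
        assert cov == pytest.approx(1 / 5)

    def test_monotone_in_tolerance(self, rng):
        x = rng.normal(size=(8, 1))
        sol = _manual_solution(x, rng.normal(size=8), rng.normal(size=(8, 2)),
                               rng.normal(size=(8, 2)))
        tols = [0.01, 0.1, 0.5, 2.0, 10.0]
        covs = [coverage(sol, tolerance=t, k=3)[0] for t in tols]
        assert all(a <= b for a, b in zip(covs, covs[1:]))

    def test_three_point_enumeration(self):
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        B = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 1.0]])
        sol = _manual_solution(x, y, np.eye(3, 2), B)
        L = sol.local_loss_matrix()
        tol = 0.1
        expected = (L <= tol).mean()
        cov, _ = coverage(sol, tolerance=tol, k=1)
        assert cov == pytest.approx(expected)


class TestFrozenEmbeddingFits:
    def test_b_step_refines_the_joint_solution(self, two_regime_fit):
        sol = two_regime_fit.solution_
        bank = fit_local_models_on_embedding(
            sol.Z, sol.dataset, lasso=sol.models.lambda_lasso,
            ridge=sol.models.lambda_ridge,
        )
        refit_loss = slisemap_loss(
            sol.Z, bank.B, sol.dataset.X, sol.dataset.Y,
            family=sol.dataset.family, lasso=sol.models.lambda_lasso,
            ridge=sol.models.lambda_ridge,
        )
        assert refit_loss <= sol.loss + 1e-6

    def test_uniform_kernel_limit_recovers_global_fit(self, rng):
        ds = Dataset.from_raw(rng.normal(size=(25, 2)), rng.normal(size=25))
        Z = np.ones((25, 2))  # all positions coincide -> uniform weights
        bank = fit_local_models_on_embedding(Z, ds, lasso=1e-3, ridge=1e-3)
        g = fit_global_model(ds, lasso=1e-3, ridge=1e-3)
        assert np.abs(bank.B - g[None, :]).max() < 1e-4

    def test_zero_ridge_floor_warns(self, rng):
        ds = Dataset.from_raw(rng.normal(size=(10, 1)), rng.normal(size=10))
        with pytest.warns(UserWarning):
            fit_local_models_on_embedding(rng.normal(size=(10, 2)), ds,
                                          lasso=0.0, ridge=0.0, max_iter=20)


def test_quality_report_is_deterministic_and_consistent(two_regime_fit):
    sol = two_regime_fit.solution_
    rep1 = quality_report(sol, k=10)
    rep2 = quality_report(sol, k=10)
    assert rep1 == rep2
    assert 0.0 <= rep1.coverage <= 1.0 and 0.0 <= rep1.nn_coverage <= 1.0
    assert rep1.local_loss == pytest.approx(local_loss(sol))
    assert rep1.tolerance_used > 0
    # on regime-structured data the local models generalise best nearby
    assert rep1.nn_coverage >= rep1.coverage
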