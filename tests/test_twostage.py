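"""Two-stage solver: loss/penalty formulas, KKT bound, oracle equivalence of
the coordinate-descent solver, and the nested-CV bookkeeping."""

import numpy as np
import pytest

from endomod import (
    FeatureSet,
    PenaltyConfig,
    enet_path,
    fit_enet_logistic,
    fit_two_stage,
    lambda_grid,
    lambda_max,
    logistic_deviance,
    penalty_evk,
    penalty_pre,
)
from tests.conftest import FAST_PEN


def total_objective(beta, b0, X, y, lam, alpha, groups, offset=None):
    """Mean deviance + penalty, the quantity both solvers minimize."""
    n = len(y)
    if groups is None:
        groups = np.full(X.shape[1], -1)
    return (logistic_deviance(beta, X, y, offset=offset, intercept=b0) / n
            + lam * penalty_pre(beta, alpha, groups))


def fista_oracle(X, y, lam, alpha, groups=None, offset=None, iters=40000):
    """Independent accelerated proximal-gradient solver for the identical
    objective (no coordinate descent involved)."""
    n, t = X.shape
    if groups is None:
        groups = np.full(t, -1)
    beta = np.zeros(t)
    b0 = 0.0
    Xa = np.hstack([np.ones((n, 1)), X])
    lip = np.linalg.eigvalsh(Xa.T @ Xa / (4 * n)).max() + lam * (1 - alpha)
    zb, zb0, tk = beta.copy(), b0, 1.0
    for _ in range(iters):
        eta = (offset if offset is not None else 0.0) + zb0 + X @ zb
        p = 1 / (1 + np.exp(-np.clip(eta, -35, 35)))
        grad = X.T @ (p - y) / n + lam * (1 - alpha) * zb
        w = zb - grad / lip
        w0 = zb0 - (p - y).mean() / lip
        new = np.zeros(t)
        th = lam * alpha / lip
        ung = groups < 0
        new[ung] = np.sign(w[ung]) * np.maximum(np.abs(w[ung]) - th, 0)
        for gid in np.unique(groups[groups >= 0]):
            m = groups == gid
            nrm = np.linalg.norm(w[m])
            if nrm > th * np.sqrt(2):
                new[m] = w[m] * (1 - th * np.sqrt(2) / nrm)
        tk1 = (1 + np.sqrt(1 + 4 * tk * tk)) / 2
        zb = new + (tk - 1) / tk1 * (new - beta)
        zb0 = w0 + (tk - 1) / tk1 * (w0 - b0)
        beta, b0, tk = new, w0, tk1
    return beta, b0


class TestDeviance:
    def test_zero_model_on_balanced_labels_is_n_log2(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        assert logistic_deviance(np.zeros(3), X, y) == pytest.approx(
            40 * np.log(2), rel=1e-12)

    def test_matches_per_sample_summation_oracle(self, rng):
        X = rng.standard_normal((30, 4))
        y = (rng.random(30) < 0.4).astype(float)
        beta = rng.standard_normal(4)
        off = rng.standard_normal(30)
        naive = sum(
            np.log(1 + np.exp(off[i] + X[i] @ beta + 0.3))
            - y[i] * (off[i] + X[i] @ beta + 0.3)
            for i in range(30)
        )
        ours = logistic_deviance(beta, X, y, offset=off, intercept=0.3)
        assert ours == pytest.approx(naive, rel=1e-10)

    def test_saturated_predictions_drive_loss_to_zero(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 0.0])
        assert logistic_deviance(np.array([1000.0]), X, y) < 1e-300


class TestPenalties:
    def test_zero_coefficients_give_zero(self):
        assert penalty_evk(np.zeros(5), 0.95) == 0.0
        assert penalty_pre(np.zeros(4), 0.95, np.array([-1, -1, 0, 0])) == 0.0

    def test_single_phase_pair_at_alpha_one(self):
        beta = np.array([3.0, 4.0])
        val = penalty_pre(beta, 1.0, np.array([0, 0]))
        assert val == pytest.approx(np.sqrt(2) * 5.0, rel=1e-12)

    def test_group_penalty_is_rotation_invariant(self, rng):
        groups = np.array([-1, 0, 0, 1, 1])
        beta = rng.standard_normal(5)
        for ang in (0.3, 1.2, -2.0):
            rot = beta.copy()
            c, s = np.cos(ang), np.sin(ang)
            rot[1], rot[2] = c * beta[1] - s * beta[2], s * beta[1] + c * beta[2]
            assert penalty_pre(rot, 0.95, groups) == pytest.approx(
                penalty_pre(beta, 0.95, groups), rel=1e-12)

    def test_unlabeled_column_rejected(self):
        with pytest.raises(ValueError):
            penalty_pre(np.ones(3), 0.95, np.array([-1, -1]))


class TestLambdaMax:
    def test_zero_design_gives_zero(self):
        assert lambda_max(np.zeros((8, 3)), np.repeat([0, 1], 4), 0.95) == 0.0

    def test_matches_gradient_norm_oracle_at_zero(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        y = np.array([1.0, 0, 1, 0])
        # p0 = 1/2 everywhere; score_j = |x_j'(y - 1/2)| / N
        expected = np.abs(X.T @ (y - 0.5)).max() / 4
        assert lambda_max(X, y, 1.0) == pytest.approx(expected, rel=1e-10)

    def test_fit_above_lambda_max_is_exactly_zero(self, rng):
        X = rng.standard_normal((60, 8))
        y = (rng.random(60) < 0.3).astype(float)
        groups = np.array([-1, -1, -1, -1, 0, 0, 1, 1])
        lm = lambda_max(X, y, 0.95, groups=groups)
        res = fit_enet_logistic(X, y, 0.95, 1.01 * lm, groups=groups)
        assert np.all(res.beta == 0)

    def test_alpha_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            lambda_max(rng.standard_normal((10, 2)), np.repeat([0, 1], 5), 0.0)


class TestSolverOracle:
    def test_dense_instance_matches_fista(self, rng):
        X = rng.standard_normal((50, 5))
        y = (rng.random(50) < 0.5).astype(float)
        lam = 0.1 * lambda_max(X, y, 0.95)
        res = fit_enet_logistic(X, y, 0.95, lam)
        bo, b0o = fista_oracle(X, y, lam, 0.95)
        ours = total_objective(res.beta, res.intercept, X, y, lam, 0.95, None)
        oracle = total_objective(bo, b0o, X, y, lam, 0.95, None)
        assert ours <= oracle + 1e-6

    def test_grouped_instance_with_offset_matches_fista(self, rng):
        X = rng.standard_normal((80, 10))
        y = (rng.random(80) < 0.25).astype(float)
        off = 0.5 * rng.standard_normal(80)
        groups = np.array([-1, -1, 0, 0, 1, 1, 2, 2, 3, 3])
        lam = 0.15 * lambda_max(X, y, 0.95, offset=off, groups=groups)
        res = fit_enet_logistic(X, y, 0.95, lam, offset=off, groups=groups)
        bo, b0o = fista_oracle(X, y, lam, 0.95, groups=groups, offset=off)
        ours = total_objective(res.beta, res.intercept, X, y, lam, 0.95,
                               groups, off)
        oracle = total_objective(bo, b0o, X, y, lam, 0.95, groups, off)
        assert ours <= oracle + 1e-6

    def test_objective_trace_is_non_increasing(self, rng):
        X = rng.standard_normal((100, 12))
        y = (rng.random(100) < 0.4).astype(float)
        lam = 0.05 * lambda_max(X, y, 0.95)
        res = fit_enet_logistic(X, y, 0.95, lam)
        trace = res.objective_trace
        assert np.all(np.diff(trace) <= 1e-10)

    def test_generative_phase_pair_enters_path_first(self, rng):
        """When the signal lives in one (sin, cos) pair, the group penalty
        should activate that pair at the largest lambda."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            theta = r.uniform(-np.pi, np.pi, 150)
            X = np.column_stack([
                r.standard_normal((150, 2)),
                np.sin(theta), np.cos(theta),
                r.standard_normal((150, 2)),
            ])
            groups = np.array([-1, -1, 0, 0, 1, 1])
            logit = 2 * np.sin(theta + 0.7)
            y = (r.random(150) < 1 / (1 + np.exp(-logit))).astype(float)
            lams = lambda_grid(lambda_max(X, y, 0.95, groups=groups), 30, 0.05)
            betas, _, _ = enet_path(X, y, 0.95, lams, groups=groups)
            first = np.argmax((betas != 0).any(axis=1))
            active = np.flatnonzero(betas[first])
            hits += set(active) <= {2, 3}
        assert hits >= 9

    def test_nonzero_count_roughly_monotone_along_path(self, rng):
        X = rng.standard_normal((100, 20))
        beta_true = np.zeros(20)
        beta_true[:5] = [2, -2, 1.5, 1, -1]
        y = (rng.random(100) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        lams = lambda_grid(lambda_max(X, y, 0.95), 25, 0.01)
        betas, _, _ = enet_path(X, y, 0.95, lams)
        nnz = (betas != 0).sum(axis=1)
        # allow rare single-step drops (exact ties) but no systematic decrease
        assert np.all(np.diff(nnz) >= -1)
        assert nnz[-1] >= nnz[0]


class TestTwoStageFit:
    def test_every_trial_held_out_exactly_once(self, two_stage_fit):
        assign = two_stage_fit.outer_assignments
        assert assign.min() == 0 and assign.max() == 4
        assert np.bincount(assign).sum() == two_stage_fit.mi.size

    def test_mi_is_the_held_out_projection(self, features0, y0, two_stage_fit):
        """Recomputing each fold's test MI from the stored fold coefficients
        must reproduce the stored MI (leakage bookkeeping)."""
        from endomod.twostage import _Scaler
        X_pre = features0.X_pre
        mask = features0.pre_groups < 0
        for k in range(5):
            te = two_stage_fit.outer_assignments == k
            sc = _Scaler(X_pre[~te], mask)
            mi_k = sc(X_pre[te]) @ two_stage_fit.fold_beta_pre[k]
            assert np.allclose(mi_k, two_stage_fit.mi[te], atol=1e-10)

    def test_same_seed_reproduces_fit(self, features0, y0, two_stage_fit):
        again = fit_two_stage(features0, y0, FAST_PEN, cv_seed=7)
        assert np.array_equal(again.outer_assignments,
                              two_stage_fit.outer_assignments)
        assert np.allclose(again.mi, two_stage_fit.mi)
        assert again.dprime_pre == two_stage_fit.dprime_pre

    def test_degenerate_all_zero_prestim_features(self, features0, y0):
        dead = FeatureSet(
            electrode_id=features0.electrode_id,
            X_pre=np.zeros_like(features0.X_pre),
            X_evk=features0.X_evk,
            pre_labels=features0.pre_labels,
            evk_labels=features0.evk_labels,
            pre_groups=features0.pre_groups,
            kept_trials=features0.kept_trials,
        )
        fit = fit_two_stage(dead, y0, FAST_PEN, cv_seed=7)
        assert np.all(fit.fold_beta_pre == 0)
        assert np.all(fit.mi == 0)
        assert fit.dprime_pre == pytest.approx(fit.dprime_evk, abs=0.15)

    def test_phase_rotation_leaves_decisions_equivariant(self, features0, y0,
                                                         two_stage_fit):
        """Applying a fixed phase offset at one frequency rotates that
        (sin, cos) feature pair; the group penalty is rotation invariant, so
        the refit d' must be unchanged."""
        import dataclasses as dc
        X = features0.X_pre.copy()
        j = 440 + 2 * 5                      # the 15 Hz pair
        ang = 1.1
        c, s = np.cos(ang), np.sin(ang)
        sin_col, cos_col = X[:, j].copy(), X[:, j + 1].copy()
        X[:, j] = c * sin_col + s * cos_col
        X[:, j + 1] = -s * sin_col + c * cos_col
        rotated = dc.replace(features0, X_pre=X)
        fit_rot = fit_two_stage(rotated, y0, FAST_PEN, cv_seed=7)
        assert fit_rot.dprime_pre == pytest.approx(two_stage_fit.dprime_pre,
                                                   abs=1e-6)
        assert np.allclose(fit_rot.mi, two_stage_fit.mi, atol=1e-5)

    def test_too_few_positives_rejected(self, features0):
        y = np.zeros(features0.n_trials, dtype=int)
        y[:5] = 1
        with pytest.raises(ValueError):
            fit_two_stage(features0, y, FAST_PEN)

    def test_non_binary_labels_rejected(self, features0):
        y = np.zeros(features0.n_trials)
        y[0] = 2.0
        with pytest.raises(ValueError):
            fit_two_stage(features0, y, FAST_PEN)
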