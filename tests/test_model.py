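"""Tests for the transport-based matrix regression model."""

import numpy as np
import pytest

from wassreg import (JWMRParams, WassersteinMatrixRegression, generate, ot,
                     support_recovery)
from wassreg import model as M
from wassreg.errors import ConfigError, DimensionError, ValidationError


class TestHistogramOp:
    @pytest.mark.parametrize(
        "x, mode, expected, nmod",
        [
            ([0.2, 0.8], "identity", [0.2, 0.8], 0),
            ([-0.1, 0.5], "clip", [0.0, 0.5], 1),
            ([-0.1, 0.5], "shift", [0.0, 0.6], 2),
            ([0.3, 0.1], "shift", [0.3, 0.1], 0),
        ],
    )
    def test_modes(self, x, mode, expected, nmod):
        out, n = M.histogram_op(x, mode)
        np.testing.assert_allclose(out, expected, atol=1e-15)
        assert n == nmod

    def test_identity_rejects_negative_naming_position(self):
        with pytest.raises(ValidationError, match="flat index 1"):
            M.histogram_op([0.2, -0.3], "identity")

    def test_unknown_mode(self):
        with pytest.raises(ConfigError):
            M.histogram_op([0.1], "bins")


@pytest.fixture(scope="module")
def small_fit():
    inst = generate(m=12, l=30, n=3, s=3, noise_sd=0.05, seed=2)
    model = WassersteinMatrixRegression(inst.A, inst.Y)
    return inst, model, model.fit()


class TestParams:
    def test_validation(self):
        with pytest.raises(ConfigError):
            JWMRParams(gamma=0.0)
        with pytest.raises(ConfigError):
            JWMRParams(lam=-1.0)
        with pytest.raises(ConfigError):
            JWMRParams(reg_mode="zero")


class TestObjective:
    def test_matches_sum_of_relaxed_solver_values(self, rng):
        """Internal consistency: the assembled objective equals the sum of the
        per-problem relaxed-transport values after a plan update."""
        inst = generate(m=6, l=8, n=3, s=2, noise_sd=0.05, seed=4)
        model = WassersteinMatrixRegression(inst.A, inst.Y)
        p = JWMRParams()
        Z = np.abs(rng.standard_normal((6, 3))) + 0.05
        lp, rp, _ = M.update_plans(Z, model.A, model.Ys_, model.C_, model.C_, p)
        J = M.objective_value(Z, lp, rp, model.A, model.Ys_, model.C_, model.C_, p)
        pred = model.A.T @ Z
        t = np.full(3, p.eps_target)
        J_direct = sum(
            ot.sinkhorn_relaxed(pred[i], model.Ys_[i], model.C_, p.gamma, p.mu)[1]
            for i in range(8))
        J_direct += p.lam * sum(
            ot.sinkhorn_relaxed(Z[j], t, model.C_, p.gamma, p.mu)[1]
            for j in range(6))
        assert J == pytest.approx(J_direct, abs=1e-8)

    def test_finite_at_floor(self):
        inst = generate(m=5, l=6, n=3, s=2, noise_sd=0.0, seed=1)
        model = WassersteinMatrixRegression(inst.A, inst.Y)
        p = JWMRParams(lam=0.0)
        Z = np.full((5, 3), p.eps_z)
        lp, rp, _ = M.update_plans(Z, model.A, model.Ys_, model.C_, model.C_, p)
        J = M.objective_value(Z, lp, rp, model.A, model.Ys_, model.C_, model.C_, p)
        assert np.isfinite(J)

    def test_dimension_mismatch(self, rng):
        p = JWMRParams()
        with pytest.raises(DimensionError):
            M.objective_value(np.ones((3, 2)), np.zeros((4, 2, 2)), np.zeros((3, 2, 2)),
                              np.ones((3, 5)), np.ones((4, 2)), np.zeros((2, 2)),
                              np.zeros((2, 2)), p)


class TestUpdatePlans:
    def test_plan_counts(self, small_fit):
        inst, model, _ = small_fit
        p = JWMRParams()
        Z = np.full((12, 3), 0.1)
        lp, rp, _ = M.update_plans(Z, model.A, model.Ys_, model.C_, model.C_, p)
        assert lp.shape == (30, 3, 3)
        assert rp.shape == (12, 3, 3)

    def test_regularizer_mass_vanishes_with_target_level(self, rng):
        inst = generate(m=8, l=10, n=3, s=2, noise_sd=0.05, seed=9)
        model = WassersteinMatrixRegression(inst.A, inst.Y)
        Z = np.abs(rng.standard_normal((8, 3))) + 0.05
        masses = []
        for eps in (1e-2, 1e-4, 1e-6):
            p = JWMRParams(eps_target=eps)
            _, rp, _ = M.update_plans(Z, model.A, model.Ys_, model.C_, model.C_, p)
            masses.append(rp.sum())
        assert masses[0] > masses[1] > masses[2]
        assert masses[2] < 0.1 * masses[0]

    def test_balanced_limit_when_prediction_matches_scores(self):
        """If (A'Z)^i == Y^i with huge mu, the loss plans are near-balanced
        optima and the marginal KL terms nearly vanish."""
        rng = np.random.default_rng(0)
        l, n = 4, 3
        A = np.eye(l)
        Y = rng.random((l, n)) + 0.2
        model = WassersteinMatrixRegression(A, Y, scale_scores=False)
        p = JWMRParams(mu=1e6)
        Z = Y.copy()  # A = I so predictions equal Y exactly
        lp, _, _ = M.update_plans(Z, model.A, model.Ys_, model.C_, model.C_, p)
        for i in range(l):
            assert ot.generalized_kl(lp[i].sum(axis=1), Y[i]) < 1e-6


class TestUpdateWeights:
    def test_gradient_matches_finite_differences(self, rng):
        m, l, n = 5, 4, 3
        A = np.abs(rng.standard_normal((m, l)))
        Z = np.abs(rng.standard_normal((m, n))) + 0.1
        loss_row = np.abs(rng.standard_normal((l, n))) + 0.1
        reg_row = np.abs(rng.standard_normal((m, n))) * 0.01
        h = 1e-6
        for mode in ("epsilon", "limit"):
            p = JWMRParams(reg_mode=mode, lam=0.7, mu=1.3)
            G = M.weight_gradient(Z, loss_row, reg_row, A, p)
            G_fd = np.zeros_like(G)
            for j in range(m):
                for k in range(n):
                    Zp, Zm = Z.copy(), Z.copy()
                    Zp[j, k] += h
                    Zm[j, k] -= h
                    G_fd[j, k] = (M._g_value(Zp, loss_row, reg_row, A, p)
                                  - M._g_value(Zm, loss_row, reg_row, A, p)) / (2 * h)
            assert np.max(np.abs(G - G_fd)) < 1e-5

    def test_identity_design_recovers_plan_marginals(self, rng):
        """With lam=0 and A=I the block objective is KL(c|Z) alone, minimized
        exactly at Z=c (clipped at the floor)."""
        l, n = 5, 3
        loss_row = np.abs(rng.standard_normal((l, n))) + 0.05
        p = JWMRParams(lam=0.0, inner_max=3000, inner_tol=1e-14)
        Z, _, warn = M.update_weights(np.full((l, n), 0.5), loss_row,
                                      np.zeros((l, n)), np.eye(l), p)
        assert not warn
        assert np.max(np.abs(Z - np.maximum(loss_row, p.eps_z))) < 1e-5

    def test_descent_contract(self, rng):
        m, l, n = 6, 9, 3
        A = np.abs(rng.standard_normal((m, l)))
        loss_row = np.abs(rng.standard_normal((l, n))) + 0.1
        reg_row = np.abs(rng.standard_normal((m, n))) * 0.01
        p = JWMRParams()
        Z0 = np.abs(rng.standard_normal((m, n))) + 0.1
        g0 = M._g_value(Z0, loss_row, reg_row, A, p)
        Z1, g1, _ = M.update_weights(Z0, loss_row, reg_row, A, p)
        assert g1 <= g0 + 1e-12
        assert np.all(Z1 >= p.eps_z)


class TestFit:
    def test_trace_monotone_and_converged(self, small_fit):
        _, _, res = small_fit
        tr = res.objective_trace
        assert np.all(tr[1:] <= tr[:-1] * (1 + 1e-9) + 1e-12)
        assert res.converged

    def test_deterministic_bit_for_bit(self, small_fit):
        inst, model, res = small_fit
        res2 = WassersteinMatrixRegression(inst.A, inst.Y).fit()
        assert np.array_equal(res.Z, res2.Z)

    def test_tiny_scores_collapse_weights_to_floor(self, rng):
        m, l, n = 8, 12, 3
        A = np.abs(rng.standard_normal((m, l)))
        Y = np.full((l, n), 1e-8)
        res = WassersteinMatrixRegression(A, Y, scale_scores=False).fit(lam=1.0)
        p = res.params
        assert np.all(np.linalg.norm(res.Z, axis=1) <= 10 * p.eps_z * np.sqrt(n))

    def test_epsilon_objective_approaches_limit_mode(self):
        """As the regularizer target level shrinks, the epsilon-mode objective
        converges to the analytic zero-target limit objective."""
        inst = generate(m=8, l=15, n=3, s=2, noise_sd=0.05, seed=6)
        model = WassersteinMatrixRegression(inst.A, inst.Y)
        res_lim = model.fit(reg_mode="limit")
        res_eps = model.fit(reg_mode="epsilon", eps_target=1e-6)
        J_lim = res_lim.objective_trace[-1]
        J_eps = res_eps.objective_trace[-1]
        assert abs(J_eps - J_lim) / abs(J_lim) < 0.01

    def test_shrinkage_monotone_in_lambda(self):
        inst = generate(m=10, l=25, n=3, s=3, noise_sd=0.05, seed=5)
        model = WassersteinMatrixRegression(inst.A, inst.Y)
        masses = [model.fit(lam=lam).Z.sum() for lam in (1e-2, 1.0, 1e2)]
        assert masses[0] + 1e-6 >= masses[1] >= masses[2] - 1e-6

    def test_recovers_planted_support(self, small_fit):
        inst, _, res = small_fit
        assert support_recovery(res.rank_features(), inst.Z_true, k=3) == 1.0

    def test_predict_round_trips_scaling(self, small_fit):
        inst, model, res = small_fit
        pred = res.predict(inst.A)
        assert pred.shape == inst.Y.shape
        # predictions live on the original score scale
        assert pred.min() > -1.0 and pred.max() < 2.0

    def test_rejects_negative_features_in_identity_mode(self, rng):
        A = rng.standard_normal((4, 6))  # signed
        Y = np.abs(rng.standard_normal((6, 3)))
        with pytest.raises(ValidationError, match="feature row"):
            WassersteinMatrixRegression(A, Y)

    def test_clip_mode_accepts_signed_features(self, rng):
        A = rng.standard_normal((8, 10)) + 0.5
        Y = np.abs(rng.standard_normal((10, 3))) + 0.1
        model = WassersteinMatrixRegression(A, Y, histogram_mode="clip")
        assert model.n_clipped_ > 0
        res = model.fit(outer_max=5)
        assert np.all(res.Z >= res.params.eps_z)

    def test_from_dataframes_aligns_samples(self, small_fit):
        import pandas as pd
        inst, _, _ = small_fit
        m, l = inst.A.shape
        samples = [f"s{i}" for i in range(l)]
        fdf = pd.DataFrame(inst.A, index=[f"f{j}" for j in range(m)], columns=samples)
        sdf = pd.DataFrame(inst.Y, index=samples, columns=["a", "b", "c"])
        model = WassersteinMatrixRegression.from_dataframes(fdf, sdf[::-1].iloc[::-1])
        np.testing.assert_allclose(model.A, inst.A)
        np.testing.assert_allclose(model.Y, inst.Y)

    def test_plot_objective_returns_axis(self, small_fit):
        import matplotlib
        matplotlib.use("Agg")
        _, _, res = small_fit
        ax = res.plot_objective()
        assert len(ax.lines) == 1
        assert len(ax.lines[0].get_xdata()) == len(res.objective_trace)

    def test_summary_mentions_dimensions(self, small_fit):
        _, _, res = small_fit
        text = res.summary()
        assert "features (m):     12" in text
        assert "lambda: 1" in text
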