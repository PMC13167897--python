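"""Penalized Newton refit, TIC, re-estimation df/BIC, hazard-ratio curves."""

import numpy as np
import pytest
from scipy.special import logit

from discboost import (BoostingConfig, ModelStructure, PenaltySpec,
                       build_reduced_basis, hazard_ratio_curve, make_dataset,
                       newton_fit, penalty_matrix, reestimation_bic_path,
                       reestimation_df, run_boosting, scenario_preset,
                       takeuchi_ic, tic_select_lambda)
from discboost.refit import penalized_loglik, score_and_information


@pytest.fixture(scope="module")
def sim_refit():
    spec = scenario_preset("highdim", n=400, P=6, seed=12)
    return make_dataset(spec)


@pytest.fixture(scope="module")
def basis_refit(sim_refit):
    return build_reduced_basis(sim_refit[0].grid, K=7)


STRUCT = ModelStructure((0, 2), (1,), ((0, 2),))


class TestPenalty:
    def test_pspline_blockdiag_shape(self, basis_refit):
        S = penalty_matrix(basis_refit, "pspline", n_tv=2)
        assert S.shape == (12, 12)
        assert np.all(S[:6, 6:] == 0)
        assert np.linalg.matrix_rank(S) == 8

    def test_empty_tv_set_zero_matrix(self, basis_refit):
        assert penalty_matrix(basis_refit, "pspline", n_tv=0).size == 0

    def test_penalized_loglik_reductions(self, sim_refit, basis_refit):
        data, _ = sim_refit
        rng = np.random.default_rng(1)
        omega = 0.1 * rng.standard_normal(STRUCT.n_params(data.grid.S, 6))
        ll0 = penalized_loglik(omega, data, basis_refit, STRUCT,
                               PenaltySpec("pspline", 0.0))
        ll2 = penalized_loglik(omega, data, basis_refit, STRUCT,
                               PenaltySpec("pspline", 2.0))
        Sth = penalty_matrix(basis_refit, "pspline", n_tv=1)
        sl = STRUCT.slices(data.grid.S, 6)["theta"]
        th = omega[sl]
        assert ll2 == pytest.approx(ll0 - 1.0 * th @ Sth @ th, abs=1e-10)
        # zero theta: penalty inert at any lambda
        omega_z = omega.copy()
        omega_z[sl] = 0.0
        for lam in (0.0, 5.0):
            assert penalized_loglik(omega_z, data, basis_refit, STRUCT,
                                    PenaltySpec("pspline", lam)) == pytest.approx(
                penalized_loglik(omega_z, data, basis_refit, STRUCT,
                                 PenaltySpec("none", 0.0)))


class TestScoreInformation:
    def test_score_matches_finite_differences(self, sim_refit, basis_refit):
        data, _ = sim_refit
        pen = PenaltySpec("pspline", 2.0)
        rng = np.random.default_rng(2)
        om = 0.1 * rng.standard_normal(STRUCT.n_params(data.grid.S, 6))
        g, _, _ = score_and_information(om, data, basis_refit, STRUCT, pen)
        eps = 1e-5
        for k in range(0, om.size, 7):
            e = np.zeros_like(om)
            e[k] = eps
            fd = (penalized_loglik(om + e, data, basis_refit, STRUCT, pen)
                  - penalized_loglik(om - e, data, basis_refit, STRUCT, pen)) / (2 * eps)
            assert g[k] == pytest.approx(fd, abs=1e-5)

    def test_information_matches_score_differences(self, sim_refit, basis_refit):
        data, _ = sim_refit
        pen = PenaltySpec("pspline", 1.0)
        rng = np.random.default_rng(3)
        om = 0.1 * rng.standard_normal(STRUCT.n_params(data.grid.S, 6))
        _, _, Ilam = score_and_information(om, data, basis_refit, STRUCT, pen)
        eps = 1e-5
        for k in (0, data.grid.S, om.size - 1):
            e = np.zeros_like(om)
            e[k] = eps
            gp, _, _ = score_and_information(om + e, data, basis_refit, STRUCT, pen)
            gm, _, _ = score_and_information(om - e, data, basis_refit, STRUCT, pen)
            np.testing.assert_allclose(-(gp - gm) / (2 * eps), Ilam[:, k], atol=1e-4)

    def test_ilambda_identity(self, sim_refit, basis_refit):
        data, _ = sim_refit
        om = np.zeros(STRUCT.n_params(data.grid.S, 6))
        _, I0, Ilam = score_and_information(om, data, basis_refit, STRUCT,
                                            PenaltySpec("pspline", 3.0))
        Sth = penalty_matrix(basis_refit, "pspline", n_tv=1)
        sl = STRUCT.slices(data.grid.S, 6)["theta"]
        expected = I0.copy()
        expected[sl, sl] += 3.0 * Sth
        np.testing.assert_allclose(Ilam, expected, atol=1e-12)


class TestNewton:
    def test_gamma_only_closed_form(self, sim_refit, basis_refit):
        data, _ = sim_refit
        fit = newton_fit(data, basis_refit, ModelStructure((), (), ()),
                         PenaltySpec("none", 0.0))
        d = np.array([len(data.failure_set(s)) for s in range(1, data.grid.S + 1)])
        r = data.risk_counts
        ok = (d > 0) & (d < r)
        np.testing.assert_allclose(fit.omega[ok], logit(d[ok] / r[ok]), atol=1e-8)

    def test_score_zero_at_unpenalized_mle(self, sim_refit, basis_refit):
        data, _ = sim_refit
        pen = PenaltySpec("none", 0.0)
        fit = newton_fit(data, basis_refit, STRUCT, pen)
        g, _, _ = score_and_information(fit.omega, data, basis_refit, STRUCT, pen)
        assert np.max(np.abs(g)) < 1e-6

    def test_lambda_zero_equals_unpenalized(self, sim_refit, basis_refit):
        data, _ = sim_refit
        f0 = newton_fit(data, basis_refit, STRUCT, PenaltySpec("none", 0.0))
        f1 = newton_fit(data, basis_refit, STRUCT, PenaltySpec("pspline", 0.0))
        assert f0.loglik == pytest.approx(f1.loglik, abs=1e-8)

    def test_parameter_recovery_ti_model(self):
        """Unpenalized refit of the oracle structure on data simulated from a
        time-independent-only model recovers phi within three standard errors."""
        from discboost import ScenarioSpec
        from discboost.simulate import GAMMA_HIGHDIM, _const, _zero

        spec = ScenarioSpec(n=4000, P=4, gamma_true=GAMMA_HIGHDIM,
                            beta_true=[_const(1.0), _zero, _const(-1.0), _zero],
                            seed=4)
        data, _ = make_dataset(spec)
        basis = build_reduced_basis(data.grid, K=7)
        structure = ModelStructure((0, 2), (), ())
        fit = newton_fit(data, basis, structure, PenaltySpec("none", 0.0))
        cov = np.linalg.inv(fit.I0)
        sl = structure.slices(data.grid.S, 6)["phi"]
        est = fit.omega[sl]
        se = np.sqrt(np.diag(cov)[sl])
        assert abs(est[0] - 1.0) < 3 * se[0]
        assert abs(est[1] - (-1.0)) < 3 * se[1]


class TestTICAndDf:
    def test_tic_at_lambda_zero_counts_parameters(self, sim_refit, basis_refit):
        data, _ = sim_refit
        fit = newton_fit(data, basis_refit, STRUCT, PenaltySpec("pspline", 0.0))
        p = STRUCT.n_params(data.grid.S, 6)
        assert takeuchi_ic(fit) == pytest.approx(-2 * fit.loglik + 2 * p, rel=1e-6)

    def test_df_reduces_to_p_at_lambda_zero(self):
        I0 = np.diag([2.0, 3.0, 4.0])
        assert reestimation_df(I0, I0) == pytest.approx(3.0)

    def test_df_scalar_closed_form(self):
        """Diagonal case: df = sum of 2r - r^2 with r = I0/(I0+lam*S)."""
        I0 = np.diag([2.0, 2.0])
        Ilam = I0 + 2.0 * np.diag([1.0, 0.0])
        r1 = 2.0 / 4.0
        assert reestimation_df(I0, Ilam) == pytest.approx((2 * r1 - r1 ** 2) + 1.0)

    def test_df_decreases_with_lambda(self, sim_refit, basis_refit):
        data, _ = sim_refit
        fit = newton_fit(data, basis_refit, STRUCT, PenaltySpec("pspline", 0.0))
        Sth = penalty_matrix(basis_refit, "pspline", n_tv=1)
        sl = STRUCT.slices(data.grid.S, 6)["theta"]
        p = STRUCT.n_params(data.grid.S, 6)
        Sfull = np.zeros((p, p))
        Sfull[sl, sl] = Sth
        dfs = [reestimation_df(fit.I0, fit.I0 + lam * Sfull)
               for lam in (0.0, 0.1, 1.0, 10.0, 1e6)]
        assert dfs[0] == pytest.approx(p)
        assert all(b <= a + 1e-9 for a, b in zip(dfs, dfs[1:]))
        assert dfs[-1] < p - 1.0

    def test_trace_term_nonincreasing_in_lambda(self, sim_refit, basis_refit):
        data, _ = sim_refit
        grid = (0.0, 0.1, 1.0, 10.0, 100.0)
        traces = []
        warm = None
        for lam in grid:
            fit = newton_fit(data, basis_refit, STRUCT,
                             PenaltySpec("pspline", lam), init=warm)
            warm = fit.omega
            M = np.linalg.solve(fit.Ilambda, fit.I0)
            traces.append(np.trace(M))
        assert all(b <= a + 1e-6 for a, b in zip(traces, traces[1:]))

    def test_degenerate_grid_returns_mle(self, sim_refit, basis_refit):
        data, _ = sim_refit
        lam, fit = tic_select_lambda(data, basis_refit, STRUCT,
                                     lambda_grid=(0.0,))
        f0 = newton_fit(data, basis_refit, STRUCT, PenaltySpec("none", 0.0))
        assert lam == 0.0
        assert fit.loglik == pytest.approx(f0.loglik, abs=1e-8)


class TestReestimationPath:
    def test_schedule_and_stop(self, sim_refit, basis_refit):
        data, _ = sim_refit
        trace = run_boosting(data, basis_refit,
                             BoostingConfig(m_max=40, stopping="reestimation_bic"))
        m_stop, fit, path = reestimation_bic_path(
            data, basis_refit, trace, every=5, lambda_grid=(0.0, 1.0))
        ms = [m for m, _ in path]
        assert ms == list(range(5, 41, 5))
        assert m_stop in ms
        assert min(b for _, b in path) == dict(path)[m_stop]
        assert fit.converged

    def test_every_one_evaluates_each_iteration(self, sim_refit, basis_refit):
        data, _ = sim_refit
        trace = run_boosting(data, basis_refit,
                             BoostingConfig(m_max=10, stopping="reestimation_bic"))
        _, _, path = reestimation_bic_path(data, basis_refit, trace, every=1,
                                           lambda_grid=(0.0,))
        assert [m for m, _ in path] == list(range(1, 11))

    def test_true_structure_found(self):
        spec = scenario_preset("highdim", n=500, P=10, seed=8)
        data, truth = make_dataset(spec)
        basis = build_reduced_basis(data.grid, K=7)
        trace = run_boosting(data, basis,
                             BoostingConfig(m_max=80, stopping="reestimation_bic"))
        m_stop, fit, _ = reestimation_bic_path(data, basis, trace,
                                               lambda_grid=(0.0, 0.1, 1.0, 10.0))
        selected = set(fit.structure.main) | set(fit.structure.tv)
        assert selected & set(truth["main"])     # finds true signal(s)


class TestOracleVersusFull:
    def test_oracle_structure_bic_beats_full(self):
        """Re-estimation BIC at the true (oracle) structure is below the BIC
        of the everything-in model on the same simulated data."""
        wins = 0
        R = 4
        for r in range(R):
            spec = scenario_preset("interaction", n=1000, seed=40 + r)
            data, truth = make_dataset(spec)
            basis = build_reduced_basis(data.grid, K=7)
            oracle = ModelStructure(tuple(truth["main"]), tuple(truth["tv"]),
                                    tuple(truth["pairs"]))
            P = data.P
            full = ModelStructure(tuple(range(P)), tuple(range(P)),
                                  tuple((j, jp) for j in range(P)
                                        for jp in range(j + 1, P)))
            bics = []
            for structure in (oracle, full):
                fit = newton_fit(data, basis, structure,
                                 PenaltySpec("pspline", 1.0), max_iter=40)
                df = reestimation_df(fit.I0, fit.Ilambda)
                bics.append(-2 * fit.loglik + np.log(data.n) * df)
            wins += bics[0] < bics[1]
        assert wins > R / 2

    def test_interaction_mae_decreases_with_n(self):
        """Oracle-structure alpha estimates tighten from n=1000 to n=4000."""
        maes = {}
        for n in (1000, 4000):
            errs = []
            for r in range(4):
                spec = scenario_preset("interaction", n=n, seed=70 + r)
                data, truth = make_dataset(spec)
                basis = build_reduced_basis(data.grid, K=7)
                structure = ModelStructure(tuple(truth["main"]),
                                           tuple(truth["tv"]),
                                           tuple(truth["pairs"]))
                fit = newton_fit(data, basis, structure, PenaltySpec("none", 0.0))
                st = fit.to_state(data, basis)
                errs.append(np.mean([abs(st.alpha[p] - truth["alpha"][p])
                                     for p in truth["pairs"]]))
            maes[n] = np.mean(errs)
        assert maes[4000] < maes[1000]


class TestHazardRatioCurve:
    def test_equal_covariates_give_unit_ratio(self, sim_refit, basis_refit):
        data, _ = sim_refit
        fit = newton_fit(data, basis_refit, STRUCT, PenaltySpec("pspline", 1.0))
        z = np.ones(data.P)
        res = hazard_ratio_curve(fit, basis_refit, z, z)
        np.testing.assert_allclose(res["estimate"], 1.0, atol=1e-12)
        np.testing.assert_allclose(res["lo"], 1.0, atol=1e-12)

    def test_ti_only_flat_curve(self, sim_refit, basis_refit):
        data, _ = sim_refit
        structure = ModelStructure((0,), (), ())
        fit = newton_fit(data, basis_refit, structure, PenaltySpec("none", 0.0))
        z1 = np.zeros(data.P)
        z1[0] = 1.0
        res = hazard_ratio_curve(fit, basis_refit, z1, np.zeros(data.P))
        phi_hat = fit.omega[structure.slices(data.grid.S, 6)["phi"]][0]
        np.testing.assert_allclose(res["estimate"], np.exp(phi_hat), atol=1e-10)
        assert np.all(res["lo"] < res["estimate"]) and np.all(res["hi"] > res["estimate"])

    def test_ci_width_against_parametric_bootstrap(self, sim_refit, basis_refit):
        """Delta-method log-scale SE matches the spread of contrasts drawn
        from the asymptotic normal of the parameters."""
        data, _ = sim_refit
        fit = newton_fit(data, basis_refit, STRUCT, PenaltySpec("pspline", 1.0))
        res = hazard_ratio_curve(fit, basis_refit,
                                 np.ones(data.P), np.zeros(data.P), level=0.95)
        cov = np.linalg.inv(fit.Ilambda)
        cov = (cov + cov.T) / 2
        rng = np.random.default_rng(9)
        draws = rng.multivariate_normal(fit.omega, cov, size=2000)
        s = data.grid.S // 2
        c = np.zeros(fit.omega.size)
        sl = STRUCT.slices(data.grid.S, 6)
        c[sl["phi"]] = 1.0
        c[sl["theta"]] = basis_refit.Bmat[s]
        c[sl["alpha"]] = 1.0
        se_boot = np.std(draws @ c, ddof=1)
        se_delta = (np.log(res["hi"][s]) - np.log(res["lo"][s])) / (2 * 1.959964)
        assert se_delta == pytest.approx(se_boot, rel=0.1)
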