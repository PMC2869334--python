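"""Constrained and unconstrained VAR(1) estimation, likelihood, PCC/PDC."""

import numpy as np
import pytest
from scipy import stats

import diaryvar as dv
from diaryvar.fit import Moments, covariance_selection
from diaryvar.structure import GraphStructure


def _brute_force_partial_corr(a, b, controls):
    """Correlate the residuals of a and b after regressing out controls."""
    if controls.shape[1]:
        coef_a, *_ = np.linalg.lstsq(controls, a, rcond=None)
        coef_b, *_ = np.linalg.lstsq(controls, b, rcond=None)
        ra, rb = a - controls @ coef_a, b - controls @ coef_b
    else:
        ra, rb = a, b
    return (ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb))


class TestUnconstrained:
    def test_equals_per_equation_ols(self, design3):
        fit = dv.fit_unconstrained(design3)
        X, Y = design3.predictors, design3.responses
        B_ols = np.linalg.lstsq(X, Y, rcond=None)[0].T
        assert np.max(np.abs(fit.beta - B_ols)) < 1e-8
        resid = Y - X @ fit.beta.T
        assert np.allclose(fit.sigma, resid.T @ resid / design3.n_obs, atol=1e-10)

    def test_statsmodels_cross_check(self):
        # single-subject panel: the pooled fit must agree with a standard
        # no-constant VAR(1) fit from an independent implementation
        from statsmodels.tsa.api import VAR

        rng = np.random.default_rng(17)
        s = GraphStructure.complete(2)
        beta, sigma = dv.make_parameters(s, seed=17)
        panel = dv.simulate_panel(
            dv.SimulationSpec(s, beta, sigma, n_subjects=1, n_times=300, seed=18)
        )
        design = dv.lagged_design(panel)
        fit = dv.fit_unconstrained(design)
        sm_res = VAR(panel.values[0]).fit(maxlags=1, trend="n")
        assert np.max(np.abs(fit.beta - sm_res.coefs[0])) < 1e-8

    def test_null_coefficients_within_asymptotic_bound(self):
        s = GraphStructure.empty(3)
        beta = np.zeros((3, 3))
        sigma = np.eye(3)
        panel = dv.simulate_panel(
            dv.SimulationSpec(s, beta, sigma, n_subjects=30, n_times=100, seed=19)
        )
        design = dv.lagged_design(panel)
        fit = dv.fit_unconstrained(design)
        assert np.max(np.abs(fit.beta)) < 3.0 / np.sqrt(design.n_obs)

    def test_duplication_invariance(self, panel3):
        single = dv.fit_unconstrained(dv.lagged_design(panel3))
        doubled_panel = dv.PanelTimeSeries(
            subject_ids=panel3.subject_ids + [s + "_copy" for s in panel3.subject_ids],
            variable_names=panel3.variable_names,
            values=np.concatenate([panel3.values] * 2),
            observed_mask=np.concatenate([panel3.observed_mask] * 2),
        )
        doubled = dv.fit_unconstrained(dv.lagged_design(doubled_panel))
        assert np.max(np.abs(single.beta - doubled.beta)) < 1e-10

    def test_univariate_reduces_to_ar1(self):
        rng = np.random.default_rng(20)
        x = np.zeros(200)
        for t in range(1, 200):
            x[t] = 0.6 * x[t - 1] + rng.normal()
        panel = dv.PanelTimeSeries(
            ["s"], ["v"], x[None, :, None], np.ones((1, 200, 1), dtype=bool)
        )
        fit = dv.fit_unconstrained(dv.lagged_design(panel))
        expected = (x[:-1] @ x[1:]) / (x[:-1] @ x[:-1])
        assert fit.beta[0, 0] == pytest.approx(expected, abs=1e-12)


class TestConstrained:
    def test_complete_structure_matches_unconstrained(self, design3):
        fu = dv.fit_unconstrained(design3)
        fc = dv.fit_constrained(design3, GraphStructure.complete(3))
        assert np.max(np.abs(fu.beta - fc.beta)) < 1e-6
        assert np.max(np.abs(fu.concentration - fc.concentration)) < 1e-6
        assert fc.loglik == pytest.approx(fu.loglik, abs=1e-6)

    def test_empty_structure_decouples_equations(self, design3):
        fit = dv.fit_constrained(design3, GraphStructure.empty(3))
        X, Y = design3.predictors, design3.responses
        for i in range(3):
            ar1 = (X[:, i] @ Y[:, i]) / (X[:, i] @ X[:, i])
            assert fit.beta[i, i] == pytest.approx(ar1, abs=1e-8)
        assert np.max(np.abs(fit.beta - np.diag(np.diag(fit.beta)))) == 0
        assert np.max(np.abs(fit.concentration - np.diag(np.diag(fit.concentration)))) == 0

    def test_exact_zeros_on_constrained_entries(self, design3, sparse3):
        structure, _, _ = sparse3
        fit = dv.fit_constrained(design3, structure)
        assert np.all(fit.beta[~structure.beta_mask()] == 0.0)
        assert np.all(fit.concentration[~structure.concentration_mask()] == 0.0)
        # sigma * concentration = identity
        assert np.max(np.abs(fit.sigma @ fit.concentration - np.eye(3))) < 1e-8

    def test_parameter_recovery_on_true_structure(self, sparse3):
        structure, beta, sigma = sparse3
        panel = dv.simulate_panel(
            dv.SimulationSpec(structure, beta, sigma, n_subjects=30, n_times=100, seed=31)
        )
        fit = dv.fit_constrained(dv.lagged_design(panel), structure)
        assert np.max(np.abs(fit.beta - beta)) < 0.1
        K_true = np.linalg.inv(sigma)
        assert np.max(np.abs(fit.concentration - K_true)) < 0.15

    def test_constrained_never_beats_unconstrained(self, design3):
        fu = dv.fit_unconstrained(design3)
        rng = np.random.default_rng(0)
        structures = list(dv.enumerate_structures(3))
        for idx in rng.choice(len(structures), 40, replace=False):
            fc = dv.fit_constrained(design3, structures[idx])
            assert fc.loglik <= fu.loglik + 1e-8


class TestCovarianceSelection:
    def test_matches_moments_on_pattern_chordal(self, design3):
        S = np.cov(design3.responses.T, bias=True)
        s = GraphStructure(3, frozenset(), {frozenset((0, 1)), frozenset((1, 2))})
        K = covariance_selection(S, s)
        Sigma = np.linalg.inv(K)
        pat = s.concentration_mask()
        assert np.max(np.abs((Sigma - S)[pat])) < 1e-8
        assert np.max(np.abs(K[~pat])) == 0.0

    def test_matches_moments_on_four_cycle(self):
        # the chordless 4-cycle is the one non-decomposable pattern at n=4,
        # exercised through iterative proportional scaling
        rng = np.random.default_rng(33)
        A = rng.normal(size=(6, 4))
        S = A.T @ A / 6 + np.eye(4)
        cyc = GraphStructure(
            4,
            frozenset(),
            {frozenset((0, 1)), frozenset((1, 2)), frozenset((2, 3)), frozenset((0, 3))},
        )
        K = covariance_selection(S, cyc)
        Sigma = np.linalg.inv(K)
        pat = cyc.concentration_mask()
        assert np.max(np.abs((Sigma - S)[pat])) < 1e-8
        assert np.max(np.abs(K[~pat])) == 0.0
        assert np.min(np.linalg.eigvalsh(K)) > 0


class TestLogLikelihood:
    def test_closed_form_at_zero(self):
        N, n = 10, 2
        design = dv.LaggedDesign(
            predictors=np.zeros((N, n)),
            responses=np.zeros((N, n)),
            subject_index=np.zeros(N, dtype=int),
            variable_names=["a", "b"],
        )
        fit = dv.VarFit(
            structure=GraphStructure.complete(n),
            beta=np.zeros((n, n)),
            concentration=np.eye(n),
            sigma=np.eye(n),
            loglik=0.0,
            n_params=7,
            n_obs=N,
            variable_names=["a", "b"],
        )
        ll = dv.log_likelihood(fit, design)
        assert ll == pytest.approx(-(N * n / 2) * np.log(2 * np.pi), abs=1e-10)

    def test_matches_per_observation_summation_oracle(self, design3, sparse3):
        structure, _, _ = sparse3
        fit = dv.fit_constrained(design3, structure)
        X, Y = design3.predictors, design3.responses
        K = fit.concentration
        _, logdet = np.linalg.slogdet(K)
        total = 0.0
        for r in range(design3.n_obs):  # naive per-observation oracle
            e = Y[r] - fit.beta @ X[r]
            total += -0.5 * 3 * np.log(2 * np.pi) + 0.5 * logdet - 0.5 * e @ K @ e
        assert dv.log_likelihood(fit, design3) == pytest.approx(total, abs=1e-6)

    def test_nested_structures_ordered(self, design3, sparse3):
        structure, _, _ = sparse3
        smaller = structure.remove_directed(1, 0)
        f_small = dv.fit_constrained(design3, smaller)
        f_big = dv.fit_constrained(design3, structure)
        assert f_small.loglik <= f_big.loglik + 1e-8


class TestInformationCriterion:
    def test_aic_formula(self):
        fit = dv.VarFit(
            structure=GraphStructure.complete(4),
            beta=np.zeros((4, 4)),
            concentration=np.eye(4),
            sigma=np.eye(4),
            loglik=-100.0,
            n_params=26,
            n_obs=100,
            variable_names=list("abcd"),
        )
        assert dv.information_criterion(fit, "aic") == pytest.approx(252.0)
        assert fit.n_params == GraphStructure.complete(4).n_params == 26

    def test_bic_exceeds_aic_for_n_at_least_8(self, design3):
        fit = dv.fit_unconstrained(design3)
        assert fit.n_obs >= 8
        assert dv.information_criterion(fit, "bic") >= dv.information_criterion(fit, "aic")


class TestPcc:
    def test_two_by_two_formula(self):
        fit = dv.VarFit(
            structure=GraphStructure.complete(2),
            beta=np.zeros((2, 2)),
            concentration=np.array([[2.0, -1.0], [-1.0, 2.0]]),
            sigma=np.linalg.inv(np.array([[2.0, -1.0], [-1.0, 2.0]])),
            loglik=0.0,
            n_params=7,
            n_obs=10,
            variable_names=["a", "b"],
        )
        pcc = dv.pcc_matrix(fit)
        assert pcc[0, 1] == pytest.approx(0.5)
        assert pcc[0, 0] == 1.0

    def test_identity_concentration_gives_zero(self):
        fit = dv.VarFit(
            structure=GraphStructure.complete(3),
            beta=np.zeros((3, 3)),
            concentration=np.eye(3),
            sigma=np.eye(3),
            loglik=0.0,
            n_params=15,
            n_obs=10,
            variable_names=list("abc"),
        )
        pcc = dv.pcc_matrix(fit)
        off = pcc[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) == 0.0

    def test_matches_residual_partial_correlation_oracle(self, design3):
        fit = dv.fit_unconstrained(design3)
        pcc = dv.pcc_matrix(fit)
        E = design3.responses - design3.predictors @ fit.beta.T
        for i in range(3):
            for j in range(i + 1, 3):
                others = [m for m in range(3) if m not in (i, j)]
                r = _brute_force_partial_corr(E[:, i], E[:, j], E[:, others])
                assert pcc[i, j] == pytest.approx(r, abs=1e-6)


class TestPdc:
    def test_zero_where_beta_zero(self, design3, sparse3):
        structure, _, _ = sparse3
        fit = dv.fit_constrained(design3, structure)
        pdc = dv.pdc_matrix(fit, design3)
        assert np.all(pdc[~structure.beta_mask()] == 0.0)
        assert np.all(np.abs(pdc) < 1.0)
        assert np.all(np.sign(pdc) == np.sign(fit.beta))

    def test_matches_double_regression_oracle(self, design3):
        fit = dv.fit_unconstrained(design3)
        pdc = dv.pdc_matrix(fit, design3)
        X, Y = design3.predictors, design3.responses
        for i in range(3):
            for j in range(3):
                others = [m for m in range(3) if m != j]
                r = _brute_force_partial_corr(Y[:, i], X[:, j], X[:, others])
                assert pdc[i, j] == pytest.approx(r, abs=1e-6)

    def test_rescaled_variant_agrees_to_first_order(self, design3):
        fit = dv.fit_unconstrained(design3)
        exact = dv.pdc_matrix(fit, design3, variant="exact")
        rescaled = dv.pdc_matrix(fit, design3, variant="rescaled")
        small = np.abs(exact) < 0.15
        assert np.max(np.abs((exact - rescaled)[small])) < 0.01


class TestSignificance:
    def test_bound_value_at_study_scale(self):
        # 35 subjects x 111 transitions = 3885 pooled observations
        bound = dv.significance_bounds(3885, level=0.95)
        assert bound == pytest.approx(stats.norm.ppf(0.975) / np.sqrt(3885), abs=1e-12)
        assert bound == pytest.approx(0.0314, abs=2e-4)

    def test_flags_use_strict_inequality(self, design3):
        fit = dv.fit_unconstrained(design3)
        assoc = dv.estimate_associations(fit, design3)
        b = assoc.test_bound
        assert np.array_equal(assoc.pdc_flags, np.abs(assoc.pdc) > b)
        # an estimate exactly at the bound is not flagged
        pdc = assoc.pdc.copy()
        pdc[0, 1] = b
        assert not (np.abs(pdc[0, 1]) > b)

    def test_scale_equivariance(self, panel3):
        design = dv.lagged_design(panel3)
        fit = dv.fit_unconstrained(design)
        scaled = panel3.copy_with_values(panel3.values * np.array([2.0, 1.0, 0.5]))
        design_s = dv.lagged_design(scaled)
        fit_s = dv.fit_unconstrained(design_s)
        # beta_ij scales by c_i / c_j; PDC and PCC are invariant
        c = np.array([2.0, 1.0, 0.5])
        assert np.max(np.abs(fit_s.beta - fit.beta * np.outer(c, 1 / c))) < 1e-8
        assert np.max(np.abs(dv.pcc_matrix(fit_s) - dv.pcc_matrix(fit))) < 1e-8
        assert np.max(
            np.abs(dv.pdc_matrix(fit_s, design_s) - dv.pdc_matrix(fit, design))
        ) < 1e-8


class TestWald:
    def test_constrained_coefficients_excluded(self, design3, sparse3):
        structure, _, _ = sparse3
        fit = dv.fit_constrained(design3, structure)
        table = dv.wald_tests(fit, design3)
        assert len(table) == 3 + len(structure.directed_edges)
        pairs = set(zip(table["response"], table["predictor"]))
        names = design3.variable_names
        assert (names[1], names[0]) not in pairs  # (0 -> 1) not in structure

    def test_strong_edge_is_highly_significant(self, design3):
        fit = dv.fit_unconstrained(design3)
        table = dv.wald_tests(fit, design3)
        names = design3.variable_names
        row = table[(table.response == names[0]) & (table.predictor == names[1])]
        assert float(row.p_value.iloc[0]) < 1e-3
        assert row.label.iloc[0] == ""

    def test_null_edge_type_i_error_rate(self):
        # 300 replicates under beta = 0, Sigma = I: the (0,1) entry should
        # reject at roughly the nominal 5% level
        rej = 0
        reps = 300
        s = dv.GraphStructure.empty(2)
        for rep in range(reps):
            panel = dv.simulate_panel(
                dv.SimulationSpec(
                    s, np.zeros((2, 2)), np.eye(2), n_subjects=10, n_times=60,
                    seed=5000 + rep,
                )
            )
            design = dv.lagged_design(panel)
            fit = dv.fit_unconstrained(design)
            table = dv.wald_tests(fit, design)
            row = table[(table.response == "x0") & (table.predictor == "x1")]
            rej += float(row.p_value.iloc[0]) < 0.05
        rate = rej / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 0.01
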