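import numpy as np
import pandas as pd
import pytest

from metfa import (
    GenomicRelationship,
    VarianceModelSpec,
    aic_value,
    fit,
    load_met_dataset,
    loglik_at,
    simulate_met,
    starting_values,
)
from metfa.reml import FitOptions

from _dense_oracle import dense_reml_loglik


class TestLoglikAgainstDenseOracle:
    def test_fa_fit_matches_dense_evaluation(self, small_fa):
        fr, ds, truth = small_fa["fit"], small_fa["dataset"], small_fa["truth"]
        Gg_eff = truth.Gg + fr.grm_ridge_used * np.eye(ds.v)
        oracle = dense_reml_loglik(ds, Gg_eff, fr.Ge, fr.sigma2_block, fr.sigma2_resid)
        assert fr.loglik == pytest.approx(oracle, abs=1e-6)

    def test_ifa_fit_matches_dense_evaluation(self, small_ifa):
        fr, ds, truth = small_ifa["fit"], small_ifa["dataset"], small_ifa["truth"]
        Gg_eff = truth.Gg + fr.grm_ridge_used * np.eye(ds.v)
        oracle = dense_reml_loglik(ds, Gg_eff, fr.Ge, fr.sigma2_block, fr.sigma2_resid)
        assert fr.loglik == pytest.approx(oracle, abs=1e-6)

    def test_loglik_at_reproduces_fit_loglik(self, small_fa):
        fr, ds, grm = small_fa["fit"], small_fa["dataset"], small_fa["grm"]
        ll = loglik_at(ds, grm, None, fr.spec, fr.params,
                       fr.sigma2_block, fr.sigma2_resid)
        assert ll == pytest.approx(fr.loglik, abs=1e-8)


class TestEquivalences:
    def test_ifa_with_square_basis_equals_fa(self):
        """With B square and full rank the integrated model is an exact
        reparameterisation of the conventional factor analytic model."""
        ds, truth = simulate_met(family="IFA", k=1, v=30, p=6, q=2, n_trials=1,
                                 n_blocks=2, missing_rate=0.03, grm="markers",
                                 n_markers=250, seed=21)
        grm = GenomicRelationship(truth.Gg, ds.genotype_levels, 0.0)
        opts = FitOptions(tol_param=1e-7, tol_loglik=1e-10, max_iter=200)
        fa = fit(ds, grm, truth.basis, VarianceModelSpec("FA", k=1), opts)
        ifa = fit(ds, grm, truth.basis, VarianceModelSpec("IFA", k=1), opts)
        assert abs(fa.loglik - ifa.loglik) <= 1e-4
        assert np.max(np.abs(fa.Ge - ifa.Ge)) <= 1e-4

    def test_single_environment_id_matches_anova_reml(self):
        """Balanced one-environment RCBD with an identity relationship:
        REML equals the closed-form ANOVA estimators."""
        rng = np.random.default_rng(10)
        v, b = 30, 4
        g = rng.normal(0, np.sqrt(0.5), v)
        blk = rng.normal(0, np.sqrt(0.3), b)
        e = rng.normal(0, np.sqrt(0.4), (v, b))
        y = 10.0 + g[:, None] + blk[None, :] + e
        rows = [("E1", "T1", f"B{j+1}", f"G{i+1}", y[i, j])
                for i in range(v) for j in range(b)]
        ds = load_met_dataset(pd.DataFrame(
            rows, columns=["env", "trial", "block", "genotype", "value"]))
        grm = GenomicRelationship(np.eye(v), ds.genotype_levels, 0.0)
        fr = fit(ds, grm, None, VarianceModelSpec("id"),
                 FitOptions(grm_ridge=0.0, tol_param=1e-8, tol_loglik=1e-12))
        gbar = y.mean(axis=1)
        bbar = y.mean(axis=0)
        mu = y.mean()
        ss_g = b * np.sum((gbar - mu) ** 2)
        ss_b = v * np.sum((bbar - mu) ** 2)
        ss_e = np.sum((y - gbar[:, None] - bbar[None, :] + mu) ** 2)
        mse = ss_e / ((v - 1) * (b - 1))
        msg = ss_g / (v - 1)
        msb = ss_b / (b - 1)
        assert fr.sigma2_resid[0] == pytest.approx(mse, rel=1e-4)
        assert fr.Ge[0, 0] == pytest.approx((msg - mse) / b, rel=1e-4)
        assert fr.sigma2_block[0] == pytest.approx((msb - mse) / v, rel=1e-3)

    def test_far_fit_is_translation_invariant(self):
        """Adding a constant to all phenotypes moves only the environment
        means, not the estimated genetic covariance."""
        ds, truth = simulate_met(family="FAR", k=1, v=25, p=6, q=2, n_trials=1,
                                 n_blocks=2, missing_rate=0.05, grm="markers",
                                 n_markers=250, seed=31)
        grm = GenomicRelationship(truth.Gg, ds.genotype_levels, 0.0)
        spec = VarianceModelSpec("FAR", k=1)
        opts = FitOptions(tol_param=1e-9, tol_loglik=1e-13, max_iter=300)
        start = starting_values(ds, spec, truth.basis, grm, opts)
        base = fit(ds, grm, truth.basis, spec, opts, start=start)
        shifted_plots = ds.plots.copy()
        shifted_plots["value"] = shifted_plots["value"] + 7.5
        ds2 = load_met_dataset(shifted_plots[["env", "trial", "block", "genotype", "value"]],
                               env_order=ds.env_levels, genotype_order=ds.genotype_levels)
        # the restricted likelihood surface is exactly invariant: evaluating
        # the shifted data at the base estimates reproduces the base loglik
        ll_shifted = loglik_at(ds2, grm, truth.basis, spec, base.params,
                               base.sigma2_block, base.sigma2_resid, opts)
        assert ll_shifted == pytest.approx(base.loglik, abs=1e-7)
        # and the base optimum stays the optimum of the shifted data: a fit
        # started there does not move (a non-invariant structure would)
        from metfa.variance import GeStructure
        structure = GeStructure(spec, ds.p, truth.basis)
        warm = {"theta": structure.pack(base.params), "s2b": base.sigma2_block,
                "s2e": base.sigma2_resid, "structure": structure}
        shifted = fit(ds2, grm, truth.basis, spec, opts, start=warm)
        assert np.max(np.abs(base.Ge - shifted.Ge)) <= 1e-6
        assert shifted.loglik == pytest.approx(base.loglik, abs=1e-6)
        np.testing.assert_allclose(shifted.tau - base.tau, 7.5, atol=1e-5)


class TestAic:
    @pytest.mark.parametrize("loglik,m,expected", [
        (10504.2, 130, -20748.4),
        (10765.4, 177, -21176.8),
        (10827.4, 199, -21256.8),
        (10971.9, 236, -21471.9),
        (0.0, 0, 0.0),
    ])
    def test_aic_convention(self, loglik, m, expected):
        # published log-likelihoods are printed to 0.1, so the implied AIC
        # carries up to 0.2 of rounding slack
        assert aic_value(loglik, m) == pytest.approx(expected, abs=0.2)

    def test_fitted_model_counts_variance_parameters_only(self, small_fa):
        fr = small_fa["fit"]
        p = fr.p
        assert fr.n_params_total == fr.n_params_genetic + 2 * p
        assert fr.aic == pytest.approx(-2 * fr.loglik + 2 * fr.n_params_total)


class TestMonotonicity:
    def test_nested_families_never_lose_likelihood(self):
        ds, truth = simulate_met(family="FA", k=2, v=30, p=6, q=2, n_trials=1,
                                 n_blocks=2, missing_rate=0.03, grm="markers",
                                 n_markers=250, seed=41)
        grm = GenomicRelationship(truth.Gg, ds.genotype_levels, 0.0)
        opts = FitOptions(max_iter=150)
        ll = {}
        for fam, k in (("comp", 0), ("mdiag", 0), ("FA", 1), ("FA", 2)):
            spec = VarianceModelSpec(fam, k=k)
            ll[(fam, k)] = fit(ds, grm, None, spec, opts).loglik
        assert ll[("mdiag", 0)] >= ll[("comp", 0)] - 1e-6
        assert ll[("FA", 2)] >= ll[("FA", 1)] - 1e-6

    def test_accepted_steps_never_decrease_loglik(self, small_ifa):
        trace = small_ifa["fit"].trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


class TestStartingValues:
    def test_deterministic_and_positive(self, small_fa):
        ds, grm = small_fa["dataset"], small_fa["grm"]
        spec = VarianceModelSpec("FA", k=1)
        s1 = starting_values(ds, spec, None, grm)
        s2 = starting_values(ds, spec, None, grm)
        np.testing.assert_array_equal(s1["theta"], s2["theta"])
        assert (s1["theta"][-ds.p:] > 0).all()      # psi starts
        assert (s1["s2e"] > 0).all() and (s1["s2b"] > 0).all()

    def test_eigen_seeded_start_captures_most_of_the_factor_gain(self):
        """On strongly one-factor data the seeded start recovers most of the
        likelihood gap between the diagonal and converged FA1 fits."""
        ds, truth = simulate_met(family="FA", k=1, v=40, p=6, q=2, n_trials=1,
                                 n_blocks=2, missing_rate=0.0, grm="markers",
                                 n_markers=300, seed=51, factor_share=0.9,
                                 env_var_genetic=0.06)
        grm = GenomicRelationship(truth.Gg, ds.genotype_levels, 0.0)
        spec = VarianceModelSpec("FA", k=1)
        opts = FitOptions()
        sv = starting_values(ds, spec, None, grm, opts)
        structure = sv["structure"]
        ll_start = loglik_at(ds, grm, None, spec, structure.unpack(sv["theta"]),
                             sv["s2b"], sv["s2e"], opts)
        ll_diag = sv["diag_fit"].loglik
        ll_fa = fit(ds, grm, None, spec, opts, start=sv).loglik
        gap = ll_fa - ll_diag
        assert gap > 0
        assert ll_fa - ll_start <= 0.05 * gap


class TestDiagnostics:
    def test_non_convergence_is_flagged(self, small_fa):
        ds, grm = small_fa["dataset"], small_fa["grm"]
        fr = fit(ds, grm, None, VarianceModelSpec("FA", k=1),
                 FitOptions(max_iter=1, tol_param=1e-12, tol_loglik=1e-14))
        assert not fr.converged

    def test_grm_ridge_recorded(self, small_fa):
        fr = small_fa["fit"]
        assert fr.grm_ridge_used > 0


class TestFixedCovariateRegression:
    def test_covariate_mean_regression_option_runs_and_matches_dense(self):
        """The optional fixed regression of environment means on covariates
        (overall mean + covariate responses + random environment residual)
        fits and agrees with an explicit dense evaluation."""
        from metfa.simulate import simulate_met
        ds, truth = simulate_met(family="rreg1", v=20, p=6, q=2, n_trials=1,
                                 n_blocks=2, missing_rate=0.0, grm="identity",
                                 seed=91)
        grm = GenomicRelationship(truth.Gg, ds.genotype_levels, 0.0)
        opts = FitOptions(fixed_covariate_regression=True, tol_param=1e-5)
        fr = fit(ds, grm, truth.basis, VarianceModelSpec("rreg1"), opts)
        assert np.isfinite(fr.loglik)
        assert fr.sigma2_omega is not None and fr.sigma2_omega > 0
        assert fr.tau.shape == (1 + 2,)          # mean + q covariate responses
        # dense check: V with the environment random effect included
        obs = ds.observed()
        env = obs["env_idx"].to_numpy()
        gen = obs["genotype_idx"].to_numpy()
        blk = obs["block_idx"].to_numpy()
        y = obs["value"].to_numpy(float)
        n, p, v = len(y), ds.p, ds.v
        X = np.hstack([np.ones((n, 1)), truth.basis.S[env]])
        Z = np.zeros((n, p * v)); Z[np.arange(n), env * v + gen] = 1
        nb = len(ds.block_levels)
        Zb = np.zeros((n, nb)); Zb[np.arange(n), blk] = 1
        Zo = np.zeros((n, p)); Zo[np.arange(n), env] = 1
        blk_env = np.zeros(nb, dtype=int); blk_env[blk] = env
        Gg_eff = truth.Gg + fr.grm_ridge_used * np.eye(v)
        V = Z @ np.kron(fr.Ge, Gg_eff) @ Z.T
        V += Zb @ np.diag(fr.sigma2_block[blk_env]) @ Zb.T
        V += fr.sigma2_omega * (Zo @ Zo.T)
        V += np.diag(fr.sigma2_resid[env])
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
        ll = -0.5 * ((n - 3) * np.log(2 * np.pi)
                     + np.linalg.slogdet(V)[1]
                     + np.linalg.slogdet(XtViX)[1]
                     + float(y @ P @ y))
        assert fr.loglik == pytest.approx(ll, abs=1e-6)
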