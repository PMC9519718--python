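import numpy as np
import pytest

from metfa.rotation import RotatedSolution, rotate_loadings
from metfa.reml import apply_triangular_constraint
from metfa.summaries import (
    env_correlation,
    environment_table,
    main_effects,
    regression_plot_data,
    variance_explained,
)
from metfa.variance import ModelSpecError, VarianceModelSpec, build_projection


def random_rotated(seed, p=8, q=3, k=2, family="IFA", psi_scale=0.1, v=25):
    rng = np.random.default_rng(seed)
    S = rng.normal(size=(p, q))
    S -= S.mean(axis=0)
    S /= np.linalg.norm(S, axis=0)
    basis = build_projection(S)
    Lstar = apply_triangular_constraint(rng.normal(size=(p, k)))
    Fstar = rng.normal(size=(v, k))
    out = rotate_loadings(Lstar, Fstar, basis.B)
    psi = psi_scale * rng.uniform(0.5, 1.5, p)
    L = out["lambda_env"]
    if L[:, 0].mean() < 0:
        L = L.copy(); L[:, 0] *= -1
        out["lambda_basis"][:, 0] *= -1
        out["scores"][:, 0] *= -1
    return RotatedSolution(
        spec=VarianceModelSpec(family, k=k), lambda_env=L,
        lambda_basis=np.linalg.lstsq(basis.B, L, rcond=None)[0],
        d=out["d"], scores=out["scores"], psi=psi, sigma2_1=None, gamma1=None,
        delta=rng.normal(scale=0.05, size=(v, p)), V=out["V"], basis=basis,
        Ge=(L * out["d"]) @ L.T + np.diag(psi),
        env_levels=[f"E{j}" for j in range(p)],
        genotype_levels=[f"G{i}" for i in range(v)],
    )


class TestVarianceExplained:
    @pytest.mark.parametrize("seed", [2, 5, 9])
    def test_additivity_identities(self, seed):
        """Overall shares equal the per-factor sums because the known and
        joint factors are orthogonal."""
        rot = random_rotated(seed)
        ve = variance_explained(rot)
        assert ve.vbar == pytest.approx(ve.v_l.sum(), abs=1e-10)
        assert ve.vbar_s == pytest.approx(ve.v_sl.sum(), abs=1e-10)
        assert ve.vbar_s <= ve.vbar + 1e-10
        assert ve.vbar <= 100 + 1e-10

    def test_per_covariate_share_matches_direct_formula(self):
        rot = random_rotated(2)
        ve = variance_explained(rot)
        S, Ls, d = rot.basis.S, rot.lambda_s, rot.d
        trG = np.trace(rot.Ge)
        for i in range(S.shape[1]):
            num = 0.0
            for jj in range(S.shape[0]):
                # s_i' S Lambda_s D lambda_s_i, written as explicit sums
                pass
            si = S[:, i]
            num = float(si @ S @ (Ls * d) @ Ls[i])
            den = float(Ls[i] @ (d * Ls[i]))
            expected = 100.0 * num**2 / (den * trG)
            assert ve.v_si[i] == pytest.approx(expected, abs=1e-10)

    def test_covariate_sum_need_not_match_overall(self):
        # known covariates are correlated, so per-covariate shares need not
        # add to the overall known share
        rot = random_rotated(11)
        ve = variance_explained(rot)
        assert ve.v_si is not None and np.isfinite(ve.v_si).all()

    def test_pure_known_single_factor(self):
        """With no latent component the known share equals the overall share
        and the factor is fully explained by the covariates."""
        rng = np.random.default_rng(3)
        p, q = 8, 3
        S = rng.normal(size=(p, q)); S -= S.mean(0); S /= np.linalg.norm(S, axis=0)
        basis = build_projection(S)
        Ls = rng.normal(size=(q, 1))
        Lstar = np.vstack([Ls, np.zeros((p - q, 1))])
        out = rotate_loadings(Lstar, rng.normal(size=(10, 1)), basis.B)
        L = out["lambda_env"]
        rot = RotatedSolution(
            spec=VarianceModelSpec("IFA", k=1), lambda_env=L,
            lambda_basis=np.linalg.lstsq(basis.B, L, rcond=None)[0],
            d=out["d"], scores=out["scores"], psi=np.full(p, 0.05),
            sigma2_1=None, gamma1=None, delta=None, V=out["V"], basis=basis,
            Ge=(L * out["d"]) @ L.T + 0.05 * np.eye(p),
        )
        ve = variance_explained(rot)
        assert ve.vbar_s == pytest.approx(ve.vbar, abs=1e-8)
        assert ve.v_ldot[0] == pytest.approx(100.0, abs=1e-8)

    def test_psi_zero_full_rank_explains_everything(self):
        rng = np.random.default_rng(8)
        p = 4
        L, _ = np.linalg.qr(rng.normal(size=(p, p)))
        d = np.array([4.0, 3.0, 2.0, 1.0])
        rot = RotatedSolution(
            spec=VarianceModelSpec("FA", k=p), lambda_env=L, lambda_basis=L,
            d=d, scores=rng.normal(size=(10, p)), psi=np.zeros(p), sigma2_1=None,
            gamma1=None, delta=None, V=np.eye(p), basis=None,
            Ge=(L * d) @ L.T,
        )
        assert variance_explained(rot).vbar == pytest.approx(100.0, abs=1e-8)

    def test_scale_invariance_of_percentages(self):
        rot = random_rotated(4)
        ve = variance_explained(rot)
        c2 = 6.25     # rescale phenotypes by 2.5: all variances scale by c^2
        scaled = RotatedSolution(
            spec=rot.spec, lambda_env=rot.lambda_env, lambda_basis=rot.lambda_basis,
            d=c2 * rot.d, scores=rot.scores, psi=c2 * rot.psi, sigma2_1=None,
            gamma1=None, delta=rot.delta, V=rot.V, basis=rot.basis,
            Ge=c2 * rot.Ge, env_levels=rot.env_levels,
            genotype_levels=rot.genotype_levels,
        )
        ve2 = variance_explained(scaled)
        assert ve2.vbar == pytest.approx(ve.vbar, abs=1e-9)
        np.testing.assert_allclose(ve2.v_si, ve.v_si, atol=1e-9)

    def test_generalised_share_equals_first_factor_share(self, small_fa):
        """The variance explained by the generalised main effects is the
        first-factor share d1 / tr(G_e)."""
        from metfa.rotation import rotate
        rot = rotate(small_fa["fit"])
        ve = variance_explained(rot)
        assert ve.v_l[0] == pytest.approx(100 * rot.d[0] / np.trace(rot.Ge),
                                          abs=1e-10)


class TestMainEffects:
    def test_fa_uniform_first_factor(self):
        p = 4
        L = np.full((p, 1), 1 / np.sqrt(p))
        scores = np.array([[1.0], [2.0], [-1.0]])
        rot = RotatedSolution(
            spec=VarianceModelSpec("FA", k=1), lambda_env=L, lambda_basis=L,
            d=np.array([2.0]), scores=scores, psi=np.full(p, 0.1), sigma2_1=None,
            gamma1=None, delta=None, V=np.eye(1), basis=None,
            Ge=2 * L @ L.T + 0.1 * np.eye(p),
            genotype_levels=["G1", "G2", "G3"],
        )
        me = main_effects(rot)
        np.testing.assert_allclose(me.effects, scores[:, 0] / np.sqrt(p), atol=1e-12)
        assert me.variance == pytest.approx(2.0 / p)

    def test_ifa_latent_mean_uses_divisor_p(self, small_ifa):
        rot = small_ifa["rot"]
        me = main_effects(rot)
        lam_bar = rot.lambda_r[:, 0].sum() / rot.p
        np.testing.assert_allclose(me.effects, lam_bar * rot.scores[:, 0], atol=1e-12)
        # identity: var(effects)/var(f1) = lambda_bar^2
        ratio = np.var(me.effects) / np.var(rot.scores[:, 0])
        assert ratio == pytest.approx(lam_bar**2, abs=1e-10)

    def test_generalised_rejected_for_simple_families(self):
        rot = random_rotated(1, family="FAR")
        with pytest.raises(ModelSpecError):
            main_effects(rot, kind="generalised")


class TestEnvCorrelation:
    def test_rank_one_full_part_is_plus_minus_one(self):
        rng = np.random.default_rng(5)
        p = 5
        L = rng.normal(size=(p, 1))
        L /= np.linalg.norm(L)
        rot = RotatedSolution(
            spec=VarianceModelSpec("FA", k=1), lambda_env=L, lambda_basis=L,
            d=np.array([1.5]), scores=rng.normal(size=(8, 1)), psi=np.full(p, 0.1),
            sigma2_1=None, gamma1=None, delta=None, V=np.eye(1), basis=None,
            Ge=1.5 * L @ L.T + 0.1 * np.eye(p),
        )
        corr, _ = env_correlation(rot, "full")
        np.testing.assert_allclose(np.abs(corr), 1.0, atol=1e-10)

    def test_matches_brute_force_cov_to_corr(self, small_ifa):
        rot = small_ifa["rot"]
        for parts in ("known", "full"):
            corr, order = env_correlation(rot, parts)
            if parts == "known":
                SL = rot.basis.S @ rot.lambda_s
                cov = (SL * rot.d) @ SL.T
            else:
                cov = rot.common_Ge()
            brute = np.zeros_like(cov)
            for a in range(rot.p):
                for b in range(rot.p):
                    brute[a, b] = cov[a, b] / np.sqrt(cov[a, a] * cov[b, b])
            np.testing.assert_allclose(corr, brute, atol=1e-10)
            assert sorted(order.tolist()) == list(range(rot.p))
            assert np.nanmax(np.abs(corr)) <= 1 + 1e-10


class TestRegressionPlots:
    def test_noise_free_points_lie_on_lines(self):
        rot = random_rotated(6, k=1)
        rot.delta = np.zeros_like(rot.delta)
        tab = regression_plot_data(rot, rot.genotype_levels[:3])
        body = tab[tab["env"] != "__main_effect__"]
        np.testing.assert_allclose(body["effect"], body["fitted"], atol=1e-10)

    def test_adjusted_second_factor_orthogonal_to_first(self):
        rot = random_rotated(7, k=2)
        rot.delta = np.zeros_like(rot.delta)
        tab = regression_plot_data(rot, rot.genotype_levels[:4])
        for g, sub in tab[tab["env"] != "__main_effect__"].groupby("genotype"):
            f2 = sub[sub["factor"] == 2].sort_values("env")
            lam1 = rot.lambda_env[:, 0]
            envs = [e for e in sorted(rot.env_levels)]
            pts = f2.set_index("env").loc[envs, "effect"].to_numpy()
            lam1_sorted = lam1[[rot.env_levels.index(e) for e in envs]]
            assert abs(pts @ lam1_sorted) < 1e-8

    def test_slope_equals_score(self, small_ifa):
        rot = small_ifa["rot"]
        tab = regression_plot_data(rot, rot.genotype_levels[:2])
        for (g, l), sub in tab.groupby(["genotype", "factor"]):
            i = rot.genotype_levels.index(g)
            assert np.allclose(sub["slope"], rot.scores[i, l - 1])

    def test_unknown_genotype_rejected(self, small_ifa):
        with pytest.raises(ModelSpecError, match="unknown"):
            regression_plot_data(small_ifa["rot"], ["NOPE"])


class TestTables:
    def test_environment_table_shape(self, small_ifa):
        tab = environment_table(small_ifa["rot"])
        assert len(tab) == small_ifa["rot"].p
        assert {"env", "variance", "v_sj", "v_j"} <= set(tab.columns)
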