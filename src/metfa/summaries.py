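"""Interpretation summaries for fitted GE variance models.

Covers genotype main effects (simple and generalised), the variance-
explained measures used for informal model selection, between-environment
additive genetic correlation matrices with a display clustering order, and
the per-factor regression-plot tables used to assess genotype performance
and stability.

All percentage measures are ratios of quadratic forms in the rotated
loadings and are therefore invariant to a global rescaling of phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .rotation import RotatedSolution
from .variance import ModelSpecError


@dataclass
class MainEffects:
    """Genotype main effects and their variance.

    ``simple`` effects are plain averages across environments (FAM/FAR);
    ``generalised`` effects are first-factor weighted averages capturing
    non-crossover GEI (FA/IFA), ``gamma* = lambda_bar_1 f_1``.
    """

    kind: str                      # "simple" | "generalised"
    effects: np.ndarray            # per-genotype vector
    variance: float                # p sigma2_g (simple) or d1 lambda_bar_1^2 (generalised)
    lam_bar: np.ndarray            # per-factor mean loadings used
    genotype_levels: list = field(default_factory=list)


def main_effects(rot: RotatedSolution, kind: str | None = None) -> MainEffects:
    """Compute simple or generalised main effects from a rotated solution.

    The generalised kind requires a family whose first factor carries
    positive loadings (FA/IFA); for the integrated family the latent mean
    loading uses divisor p, ``lambda_bar_r1 = 1' lambda_r1 / p``.
    """
    fam = rot.spec.family
    if kind is None:
        kind = "simple" if fam in ("FAM", "FAR") else "generalised"
    p, k = rot.p, rot.k

    if kind == "simple":
        if fam == "FAM":
            lam_bar = rot.lambda_env.mean(axis=0)
            eff = rot.gamma1 + np.sqrt(p) * rot.scores @ lam_bar
            sigma2_g = rot.sigma2_1 + float(np.sum(rot.d * lam_bar**2))
            return MainEffects("simple", eff, p * sigma2_g, lam_bar, rot.genotype_levels)
        if fam == "FAR":
            lam_g = rot.lambda_g
            eff = rot.scores @ lam_g / np.sqrt(p)
            sigma2_g = float(np.sum(rot.d * lam_g**2)) / p
            return MainEffects("simple", eff, p * sigma2_g, lam_g / np.sqrt(p),
                               rot.genotype_levels)
        raise ModelSpecError(f"simple main effects are not defined for {fam}")

    if kind == "generalised":
        if fam == "FA":
            lam_bar1 = float(rot.lambda_env[:, 0].mean())
        elif fam == "IFA":
            lam_bar1 = float(rot.lambda_r[:, 0].sum() / p)
        else:
            raise ModelSpecError(f"generalised main effects are not defined for {fam}")
        if rot.lambda_env[:, 0].mean() <= 0:
            raise ModelSpecError("first factor is not positively oriented")
        eff = lam_bar1 * rot.scores[:, 0]
        var = float(rot.d[0]) * lam_bar1**2
        lam_bar = np.zeros(k)
        lam_bar[0] = lam_bar1
        return MainEffects("generalised", eff, var, lam_bar, rot.genotype_levels)

    raise ModelSpecError(f"unknown main effect kind {kind!r}")


@dataclass
class VarianceExplained:
    """Percentage-of-additive-genetic-variance summaries.

    ``vbar`` is the overall share captured by the common factors,
    ``vbar_s`` the share captured through the known covariates; ``v_j`` and
    ``v_sj`` are the per-environment analogues, ``v_l``/``v_sl`` the
    per-factor shares, ``v_si`` the per-covariate share, ``v_li`` the
    factor-by-covariate decomposition and ``v_ldot`` the share of each
    factor explained by all known covariates together.
    """

    vbar: float
    vbar_s: float | None
    v_j: np.ndarray
    v_sj: np.ndarray | None
    v_l: np.ndarray
    v_sl: np.ndarray | None
    v_si: np.ndarray | None
    v_li: np.ndarray | None          # k x q
    v_ldot: np.ndarray | None
    trace_Ge: float


def variance_explained(rot: RotatedSolution) -> VarianceExplained:
    """All variance-explained measures for a rotated factor solution.

    Per-environment measures are ratios of diagonals of the relevant
    quadratic forms to the diagonal of G_e; they may exceed the overall
    factor share for single environments because known and latent
    covariates are not orthogonal environment-by-environment (no clipping
    is applied).
    """
    trG = float(np.trace(rot.Ge))
    if trG <= 0:
        raise ModelSpecError("tr(G_e) must be positive")
    d = rot.d
    common = rot.common_Ge()
    v_l = 100.0 * d / trG
    vbar = 100.0 * float(np.trace(common)) / trG
    if rot.spec.family == "FAM":
        # include the explicit main-effect variance in the common part
        vbar = 100.0 * (rot.sigma2_1 * rot.p + float(np.trace(common))) / trG
    v_j = 100.0 * np.diag(common) / np.diag(rot.Ge)

    vbar_s = v_sj = v_si = v_sl = v_li = v_ldot = None
    if rot.spec.family in ("FAR", "IFA"):
        S = rot.basis.S
        Ls = rot.lambda_s
        known = (S @ Ls * d) @ (S @ Ls).T
        vbar_s = 100.0 * float(np.trace(known)) / trG
        v_sj = 100.0 * np.diag(known) / np.diag(rot.Ge)
        StS = S.T @ S
        v_sl = 100.0 * d * np.einsum("ik,ij,jk->k", Ls, StS, Ls) / trG
        # per-covariate share: squared covariance of covariate i with the
        # known-factor regression, normalised by the covariate's own slope
        # variance
        q = S.shape[1]
        v_si = np.zeros(q)
        for i in range(q):
            num = float(S[:, i] @ S @ (Ls * d) @ Ls[i])
            den = float(Ls[i] @ (d * Ls[i]))
            v_si[i] = 100.0 * num**2 / (den * trG) if den > 0 else 0.0
        # factor-by-covariate decomposition on the composite loadings
        v_li = 100.0 * (S.T @ rot.lambda_env).T ** 2       # k x q
        v_ldot = 100.0 * np.einsum("ik,ij,jk->k", Ls, StS, Ls)
    return VarianceExplained(vbar, vbar_s, v_j, v_sj, v_l, v_sl, v_si, v_li,
                             v_ldot, trG)


def env_correlation(
    rot: RotatedSolution,
    parts: str = "full",
    include_psi: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Between-environment additive genetic correlation matrix.

    ``parts='known'`` uses the known-covariate regression part
    ``S Lambda_s D Lambda_s' S'``; ``parts='full'`` the common-factor part
    ``Lambda D Lambda'``.  Specific variances are excluded by default so the
    two parts are comparable; ``include_psi`` adds them.  Returns the
    correlation matrix (NaN rows for zero-variance environments) and a
    display ordering from average-linkage agglomerative clustering on
    1 - correlation (deterministic tie-break by environment index).
    """
    if parts == "known":
        if rot.spec.family not in ("FAR", "IFA"):
            raise ModelSpecError("known part requires known-covariate loadings")
        SL = rot.basis.S @ rot.lambda_s
        cov = (SL * rot.d) @ SL.T
    elif parts == "full":
        cov = rot.common_Ge()
    else:
        raise ModelSpecError("parts must be 'known' or 'full'")
    if include_psi:
        cov = cov + np.diag(rot.psi)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))

    ok = sd > 0
    order = np.arange(len(sd))
    if ok.sum() > 2:
        sub = corr[np.ix_(ok, ok)]
        dist = np.clip(1.0 - sub, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        link = sch.linkage(ssd.squareform(dist, checks=False), method="average")
        leaves = sch.leaves_list(link)
        idx_ok = np.flatnonzero(ok)
        order = np.concatenate([idx_ok[leaves], np.flatnonzero(~ok)])
    return corr, order


def regression_plot_data(
    rot: RotatedSolution,
    genotypes: list[str],
) -> pd.DataFrame:
    """Per-factor regression-plot table for the requested genotypes.

    For factor l the x-axis holds the composite environment loadings, the
    fitted line passes through the origin with slope equal to the genotype's
    factor-l score, and the plotted GE effects are adjusted for the
    contributions of factors 1..l-1 (deviations stay in the points).  The
    main-effect marker sits at the mean loading of factor 1.
    """
    gmap = {g: i for i, g in enumerate(rot.genotype_levels)}
    missing = [g for g in genotypes if g not in gmap]
    if missing:
        raise ModelSpecError(f"unknown genotypes: {missing}")
    L = rot.lambda_env
    F = rot.scores
    # full GE effects of the factor part plus deviations (FAM intercepts are
    # main effects, not GEI, and are excluded from the regression plane)
    rows = []
    lam_bar1 = float(L[:, 0].mean())
    for g in genotypes:
        i = gmap[g]
        u = F[i] @ L.T + (rot.delta[i] if rot.delta is not None else 0.0)
        for l in range(rot.k):
            adj = u - F[i, : l] @ L[:, : l].T
            for j in range(rot.p):
                rows.append({
                    "genotype": g, "factor": l + 1,
                    "env": rot.env_levels[j] if rot.env_levels else j,
                    "loading": L[j, l],
                    "effect": adj[j],
                    "fitted": F[i, l] * L[j, l],
                    "slope": F[i, l],
                })
        rows.append({
            "genotype": g, "factor": 1, "env": "__main_effect__",
            "loading": lam_bar1, "effect": lam_bar1 * F[i, 0],
            "fitted": lam_bar1 * F[i, 0], "slope": F[i, 0],
        })
    return pd.DataFrame(rows)


def environment_table(rot: RotatedSolution) -> pd.DataFrame:
    """Per-environment summary: variance, variance-explained and loadings."""
    ve = variance_explained(rot)
    out = pd.DataFrame({
        "env": rot.env_levels or list(range(rot.p)),
        "variance": np.diag(rot.Ge),
        "v_j": ve.v_j,
    })
    if ve.v_sj is not None:
        out.insert(2, "v_sj", ve.v_sj)
    for l in range(rot.k):
        out[f"lambda_{l + 1}"] = rot.lambda_env[:, l]
    return out


def covariate_table(rot: RotatedSolution) -> pd.DataFrame:
    """Per-covariate summary: signed covariance, variance share, loadings.

    The "covariance" column is the signed square root of the per-covariate
    variance contribution (an interpretation choice; the sign comes from
    the covariate's projection on the dominant factor contribution).
    """
    if rot.spec.family not in ("FAR", "IFA"):
        raise ModelSpecError("covariate table requires known-covariate loadings")
    ve = variance_explained(rot)
    S = rot.basis.S
    Ls = rot.lambda_s
    proj = S.T @ S @ (Ls * rot.d) @ Ls.T  # q x q contribution matrix
    signed = np.sign(np.diag(proj)) * np.sqrt(np.abs(np.diag(proj)))
    names = getattr(rot.basis, "names", None) or [f"cov{i + 1}" for i in range(S.shape[1])]
    out = pd.DataFrame({"covariate": names, "covariance": signed, "v_si": ve.v_si})
    for l in range(rot.k):
        out[f"lambda_s{l + 1}"] = Ls[:, l]
    return out
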