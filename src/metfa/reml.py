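"""Average-information REML for multi-environment trial mixed models.

The observation model is

    y = X tau + Z u + Z_p u_p + e,

with fixed environment means ``tau`` (optionally an overall mean plus a
regression on known covariates with a residual environment effect), random
GE effects ``u`` with var(u) = G_e (x) G_g for any supported G_e family,
random replicate-block effects ``u_p`` with a separate variance per
environment, and independent residuals with a separate variance per
environment.  Estimation maximises the residual log-likelihood with
average-information (AI) updates, step-halving when a step would decrease
the likelihood, and floors on variance parameters.

The implementation works on the mixed-model equations at the level of
genotype-by-environment cells: all plot information enters through per-
environment cross-products, and the vp x vp genetic precision
``G_e^-1 (x) G_g^-1`` is dense.  Identifiability during estimation follows
the usual factor analytic constraint scheme: the score covariance is fixed
at I_k and the upper-right triangle of the (stacked) loadings is zero;
rotation to principal axes is a separate post-fit step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg.lapack import dpotrf, dpotri, dpotrs

from .io import GenomicRelationship, METDataset
from .variance import (
    CovariateBasis,
    GeParameters,
    GeStructure,
    ModelSpecError,
    VarianceModelSpec,
    PSI_FLOOR,
)

LOG2PI = np.log(2.0 * np.pi)


class RemlError(RuntimeError):
    pass


@dataclass
class FitOptions:
    """Tuning knobs of the REML fit."""

    max_iter: int = 80
    tol_param: float = 1e-6          # max relative parameter change
    tol_loglik: float = 1e-8         # relative log-likelihood change
    psi_floor: float = PSI_FLOOR
    grm_ridge: float | None = None   # None: 1e-5 * mean diagonal of G_g
    fixed_covariate_regression: bool = False   # overall mean + S tau_s + omega
    max_halvings: int = 20
    ai_ridge: float = 1e-10
    verbose: bool = False
    seed: int = 0                    # reserved for randomised restarts


@dataclass
class FittedModel:
    """REML estimates, EBLUPs and fit diagnostics for one variance model."""

    spec: VarianceModelSpec
    params: GeParameters             # genetic parameters (estimation scale, D = I)
    Ge: np.ndarray                   # p x p assembled genetic covariance
    sigma2_block: np.ndarray         # per-environment block variance
    sigma2_resid: np.ndarray         # per-environment residual variance
    sigma2_omega: float | None
    tau: np.ndarray                  # fixed-effect estimates
    loglik: float
    n_params_genetic: int
    n_params_total: int
    converged: bool
    n_iter: int
    trace: list
    w: np.ndarray                    # v x p matrix, (G^-1 u_hat) by environment
    gg_w: np.ndarray                 # v x p matrix, G_g @ w (per environment)
    u_hat: np.ndarray                # v x p EBLUPs of GE effects
    f_star: np.ndarray | None        # v x k EBLUP scores under D = I (factor fams)
    delta: np.ndarray | None         # v x p EBLUP deviations (factor fams)
    gamma1: np.ndarray | None        # v EBLUP intercepts (FAM)
    basis: CovariateBasis | None
    grm_ridge_used: float
    env_levels: list
    genotype_levels: list

    @property
    def aic(self) -> float:
        return aic_value(self.loglik, self.n_params_total)

    @property
    def p(self) -> int:
        return self.Ge.shape[0]

    @property
    def v(self) -> int:
        return self.w.shape[0]


def aic_value(loglik: float, n_variance_params: int) -> float:
    """AIC = -2 loglik + 2 m, counting estimated variance parameters only."""
    return -2.0 * loglik + 2.0 * n_variance_params


# ---------------------------------------------------------------------------
# design cache


class _Design:
    """Per-dataset sparse design and cross-products for the MME."""

    def __init__(self, ds: METDataset, options: FitOptions,
                 basis: CovariateBasis | None):
        obs = ds.observed()
        self.p = ds.p
        self.v = ds.v
        self.n = len(obs)
        self.env = obs["env_idx"].to_numpy()
        self.gen = obs["genotype_idx"].to_numpy()
        self.block = obs["block_idx"].to_numpy()
        self.y = obs["value"].to_numpy(dtype=float)
        self.nb = len(ds.block_levels)
        # environment of each block level
        blk_env = np.zeros(self.nb, dtype=int)
        blk_env[obs["block_idx"].to_numpy()] = obs["env_idx"].to_numpy()
        self.block_env = blk_env
        self.n_j = np.bincount(self.env, minlength=self.p)
        self.nb_j = np.bincount(blk_env, minlength=self.p)

        self.eq2 = options.fixed_covariate_regression
        if self.eq2:
            if basis is None:
                raise RemlError("fixed covariate regression requires a covariate basis")
            self.px = 1 + basis.q
            Xd = np.hstack([np.ones((self.n, 1)), basis.S[self.env]])
            self.X = sp.csr_matrix(Xd)
            self.n_omega = self.p
        else:
            self.px = self.p
            self.X = sp.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), self.env)), shape=(self.n, self.p)
            )
            self.n_omega = 0

        rows = np.arange(self.n)
        Zb = sp.csr_matrix((np.ones(self.n), (rows, self.block)), shape=(self.n, self.nb))
        cell = self.env * self.v + self.gen
        Zc = sp.csr_matrix((np.ones(self.n), (rows, cell)), shape=(self.n, self.p * self.v))
        # cells first: the dense genetic block of the coefficient matrix is
        # then contiguous, which makes its Kronecker fill cheap
        blocks = [Zc, self.X, Zb]
        if self.n_omega:
            Zo = sp.csr_matrix((np.ones(self.n), (rows, self.env)), shape=(self.n, self.p))
            blocks.append(Zo)
        self.W = sp.hstack(blocks, format="csr")
        self.off_u = 0
        self.off_x = self.p * self.v
        self.off_b = self.off_x + self.px
        self.off_o = self.off_b + self.nb
        self.dim = self.off_o + self.n_omega

        # per-environment cross-products
        self.gram = []
        self.wty = []
        self.yty = np.zeros(self.p)
        self.gram_lo = []
        for j in range(self.p):
            sel = self.env == j
            Wj = self.W[sel]
            yj = self.y[sel]
            gj = (Wj.T @ Wj).tocoo()
            self.gram.append(gj)
            # lower-triangle index pairs for reading a lower-filled inverse
            self.gram_lo.append((np.maximum(gj.row, gj.col), np.minimum(gj.row, gj.col)))
            self.wty.append(Wj.T @ yj)
            self.yty[j] = float(yj @ yj)
        self._kbuf = None


# ---------------------------------------------------------------------------
# likelihood evaluation


class _State:
    __slots__ = ("m2ll", "chol", "dscale", "sol", "rhs", "logdet_Ge", "Ge", "Ge_inv", "ok")


def _safe_chol_inv(A: np.ndarray, what: str):
    c, info = dpotrf(A, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(what)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv, info = dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(what)
    inv = np.tril(inv) + np.tril(inv, -1).T
    return logdet, inv


def _evaluate(design: _Design, structure: GeStructure, Gg_inv: np.ndarray,
              logdet_Gg: float, theta: np.ndarray, s2b: np.ndarray,
              s2e: np.ndarray, s2o: float | None) -> _State:
    """Assemble and factorise the MME; return -2 * restricted log-likelihood."""
    st = _State()
    st.ok = False
    p, v, nb = design.p, design.v, design.nb
    try:
        Ge = structure.ge(theta)
        st.Ge = Ge
        st.logdet_Ge, st.Ge_inv = _safe_chol_inv(Ge, "G_e not positive definite")
    except np.linalg.LinAlgError:
        st.m2ll = np.inf
        return st

    rinv = 1.0 / s2e
    Aw = design.gram[0] * rinv[0]
    for j in range(1, p):
        Aw = Aw + design.gram[j] * rinv[j]
    C = Aw.toarray()
    db = 1.0 / s2b[design.block_env]
    idx = np.arange(design.off_b, design.off_b + nb)
    C[idx, idx] += db
    if design.n_omega:
        io = np.arange(design.off_o, design.off_o + p)
        C[io, io] += 1.0 / s2o
    vp = p * v
    if design._kbuf is None:
        design._kbuf = np.empty((vp, vp))
    K = design._kbuf
    np.einsum('jk,ab->jakb', st.Ge_inv, Gg_inv, out=K.reshape(p, v, p, v))
    C[:vp, :vp] += K

    # symmetric Jacobi rescaling: collapsing variance components make C very
    # ill-conditioned; equilibration keeps logdet and solves accurate
    dscale = np.sqrt(np.maximum(np.diag(C), 1e-300))
    C /= dscale[:, None]
    C /= dscale[None, :]
    c, info = dpotrf(C, lower=1, overwrite_a=1)
    if info != 0:
        st.m2ll = np.inf
        return st
    st.chol = c
    st.dscale = dscale
    logdetC = 2.0 * np.sum(np.log(np.diag(c))) + 2.0 * np.sum(np.log(dscale))

    rhs = design.wty[0] * rinv[0]
    for j in range(1, p):
        rhs = rhs + design.wty[j] * rinv[j]
    sol, info = dpotrs(c, rhs / dscale, lower=1)
    sol = sol / dscale
    st.rhs, st.sol = rhs, sol
    yRy = float(np.sum(design.yty * rinv))
    yPy = yRy - float(rhs @ sol)

    m2ll = (design.n - design.px) * LOG2PI
    m2ll += float(np.sum(design.n_j * np.log(s2e)))
    m2ll += float(np.sum(design.nb_j * np.log(s2b)))
    if design.n_omega:
        m2ll += p * np.log(s2o)
    m2ll += v * st.logdet_Ge + p * logdet_Gg
    m2ll += logdetC + yPy
    st.m2ll = m2ll
    st.ok = True
    return st


# ---------------------------------------------------------------------------
# starting values


def _moment_starts(design: _Design):
    """Per-environment phenotypic variances split into crude components."""
    var_j = np.zeros(design.p)
    for j in range(design.p):
        yj = design.y[design.env == j]
        var_j[j] = np.var(yj, ddof=1) if len(yj) > 1 else 1.0
    var_j = np.maximum(var_j, 1e-8)
    return var_j


def starting_values(
    dataset: METDataset,
    spec: VarianceModelSpec,
    basis: CovariateBasis | None = None,
    grm: GenomicRelationship | None = None,
    options: FitOptions | None = None,
    _diag_fit: "FittedModel | None" = None,
) -> dict:
    """Deterministic starting values for the AI-REML iteration.

    Non-factor families start from per-environment moment splits.  Factor
    families first fit the ``diag`` model for variance scales, then seed the
    loadings from the leading eigenvectors of a noise-corrected covariance
    matrix of genotype-by-environment cell means, with specific variances
    set to the part of each environment's genetic variance the leading
    factors leave unexplained.
    """
    options = options or FitOptions()
    design = _Design(dataset, options, basis)
    var_j = _moment_starts(design)
    p = design.p
    fam = spec.family
    structure = GeStructure(spec, p, basis)

    s2b = 0.1 * var_j
    s2e = 0.5 * var_j
    vbar = float(var_j.mean())

    if fam in ("id", "diag", "comp", "mdiag", "rreg1", "rreg2"):
        g_j = 0.4 * var_j
        if fam == "id":
            theta = np.array([0.4 * vbar])
        elif fam == "diag":
            theta = g_j.copy()
        elif fam == "comp":
            theta = np.array([0.2 * vbar, 0.2 * vbar])
        elif fam == "mdiag":
            theta = np.concatenate([[0.2 * vbar], 0.2 * var_j])
        elif fam == "rreg1":
            scale = float(np.mean(np.sum(basis.S**2, axis=1)))
            theta = np.concatenate([[0.2 * vbar], [0.1 * vbar / max(scale, 1e-8)], ])
            theta = np.concatenate([theta, 0.2 * var_j])
        else:  # rreg2
            scale = float(np.mean(basis.S**2)) * p
            theta = np.concatenate([[0.2 * vbar],
                                    np.full(basis.q, 0.1 * vbar / max(scale, 1e-8)),
                                    0.2 * var_j])
        return {"theta": theta, "s2b": s2b, "s2e": s2e, "structure": structure}

    # factor families: seed from a diag fit + sample genetic correlation.
    # The diag fit only supplies per-environment variance scales, so it runs
    # on a genotype subset with loose tolerances when v is large.
    if _diag_fit is None:
        loose = FitOptions(max_iter=30, tol_param=1e-4, tol_loglik=1e-7,
                           psi_floor=options.psi_floor, grm_ridge=options.grm_ridge)
        if dataset.v > 100:
            keep = dataset.genotype_levels[:100]
            from .io import load_met_dataset
            sub_plots = dataset.plots[dataset.plots["genotype"].isin(set(keep))]
            sub = load_met_dataset(sub_plots[["env", "trial", "block", "genotype", "value"]],
                                   env_order=dataset.env_levels, genotype_order=keep)
            diag_fit = fit(sub, grm, None, VarianceModelSpec("diag"), loose)
        else:
            diag_fit = fit(dataset, grm, None, VarianceModelSpec("diag"), loose)
    else:
        diag_fit = _diag_fit
    s2b = np.maximum(diag_fit.sigma2_block, 1e-10 * vbar)
    s2e = np.maximum(diag_fit.sigma2_resid, 1e-8 * vbar)

    # noise-corrected covariance of genotype x environment cell means:
    # the residual contribution to the diagonal is removed and the scale of
    # the relationship matrix divided out, which keeps the eigen-seeded
    # loadings on the genetic scale instead of the attenuated sample scale
    cnt = np.zeros((design.v, p))
    tot = np.zeros((design.v, p))
    np.add.at(cnt, (design.gen, design.env), 1.0)
    np.add.at(tot, (design.gen, design.env), design.y)
    with np.errstate(invalid="ignore"):
        cells = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    cells = cells - np.nanmean(cells, axis=0)
    Cov = np.zeros((p, p))
    for a in range(p):
        for b in range(a, p):
            ok = ~np.isnan(cells[:, a]) & ~np.isnan(cells[:, b])
            if ok.sum() > 2:
                Cov[a, b] = Cov[b, a] = float(np.mean(cells[ok, a] * cells[ok, b]))
    noise = s2e / np.maximum(cnt.mean(axis=0), 1e-9)
    gscale = float(np.mean(np.diag(grm.G))) if grm is not None else 1.0
    Ge0 = (Cov - np.diag(noise)) / max(gscale, 1e-12)
    Ge0 = 0.5 * (Ge0 + Ge0.T)
    g_j = np.maximum(np.diag(Ge0), 1e-3 * vbar)

    sig1 = 0.0
    if fam == "FAM":
        off = Ge0[~np.eye(p, dtype=bool)]
        sig1 = max(float(np.mean(off)), 0.05 * float(np.mean(g_j)))
        Ge0 = Ge0 - sig1 * np.ones((p, p))
    evals, evecs = np.linalg.eigh(Ge0)
    order = np.argsort(evals)[::-1]
    k = spec.k
    lam_env = evecs[:, order[:k]] * np.sqrt(np.maximum(evals[order[:k]], 0.01 * np.mean(g_j)))
    if fam in ("FA", "FAM"):
        L = lam_env
    elif fam == "FAR":
        L = np.linalg.lstsq(basis.A, lam_env, rcond=None)[0]
    else:  # IFA
        L = np.linalg.lstsq(basis.B, lam_env, rcond=None)[0]
        if spec.kr < k:
            L[basis.q:, spec.kr:] = 0.0
    L = apply_triangular_constraint(L)
    if fam == "IFA" and spec.kr < k:
        L[basis.q:, spec.kr:] = 0.0
        L = apply_triangular_constraint(L)
        L[basis.q:, spec.kr:] = 0.0
    # specific variances: what the leading factors leave unexplained
    psi0 = np.maximum(g_j - np.sum(lam_env**2, axis=1), 0.05 * g_j)
    psi0 = np.maximum(psi0, options.psi_floor)
    params = GeParameters(spec, loadings=L, psi=psi0, sigma2_1=sig1 if fam == "FAM" else None)
    theta = structure.pack(params)
    return {"theta": theta, "s2b": s2b, "s2e": s2e, "structure": structure,
            "diag_fit": diag_fit}


def apply_triangular_constraint(L: np.ndarray) -> np.ndarray:
    """Rotate loadings so the upper-right triangle of the leading rows is zero.

    Uses the LQ decomposition of the top k x k block; the rotated loadings
    span the same column space and satisfy the estimation constraints.
    """
    k = L.shape[1]
    top = L[:k, :]
    # LQ of top block: top = L_tri Q  ->  L @ Q.T has lower-triangular top block
    Q, R = np.linalg.qr(top.T)
    out = L @ Q
    # enforce non-negative diagonal for determinism
    for c in range(min(k, out.shape[0])):
        if out[c, c] < 0:
            out[:, c] = -out[:, c]
    tri = np.triu_indices(min(k, out.shape[0]), 1)
    out[tri] = 0.0
    return out


# ---------------------------------------------------------------------------
# main fit


def fit(
    dataset: METDataset,
    grm: GenomicRelationship,
    basis: CovariateBasis | None,
    spec: VarianceModelSpec,
    options: FitOptions | None = None,
    start: dict | None = None,
) -> FittedModel:
    """Fit the mixed model by average-information REML.

    Parameters
    ----------
    dataset
        Loaded MET phenotypes.
    grm
        Genomic relationship between the dataset's genotypes.  A solve-time
        diagonal ridge (default ``1e-5 x mean diagonal``) keeps the centred
        genomic relationship matrix invertible; the value used is recorded
        on the result.
    basis
        Known-covariate basis; required by the rreg/FAR/IFA families.
    spec, options, start
        Variance model family, fit options and optional starting values
        (as returned by :func:`starting_values`).
    """
    options = options or FitOptions()
    spec.validate(dataset.p, basis.q if basis is not None else None)
    grm = grm.reorder(dataset.genotype_levels)
    design = _Design(dataset, options, basis)
    p, v = design.p, design.v

    ridge = options.grm_ridge
    if ridge is None:
        ridge = 1e-5 * float(np.mean(np.diag(grm.G)))
    Gg = grm.G + ridge * np.eye(v)
    logdet_Gg, Gg_inv = _safe_chol_inv(Gg, "G_g not positive definite after ridge")

    if start is None:
        start = starting_values(dataset, spec, basis, grm, options)
    structure: GeStructure = start["structure"]
    theta = np.asarray(start["theta"], dtype=float).copy()
    s2b = np.asarray(start["s2b"], dtype=float).copy()
    s2e = np.asarray(start["s2e"], dtype=float).copy()
    s2o = float(start.get("s2o", np.mean(s2b))) if design.n_omega else None

    var_mask = structure.variance_mask()
    vbar = float(np.mean(_moment_starts(design)))
    # floors are scale-aware: collapsing variances enter the mixed-model
    # equations through their reciprocals, so a floor far below the data
    # scale destroys the precision of the likelihood identity
    var_floor = 1e-4 * vbar
    psi_floor = max(options.psi_floor, 1e-4 * vbar)
    g_floor = np.full(structure.n_params, -np.inf)
    g_floor[var_mask] = var_floor
    if structure.n_psi:
        g_floor[-structure.n_psi:] = psi_floor

    state = _evaluate(design, structure, Gg_inv, logdet_Gg, theta, s2b, s2e, s2o)
    if not state.ok:
        raise RemlError("starting values give a singular mixed-model system")

    trace = [(-0.5 * state.m2ll)]
    converged = False
    n_iter = 0
    for it in range(1, options.max_iter + 1):
        n_iter = it
        score, AI, aux = _score_and_ai(design, structure, Gg, Gg_inv, theta,
                                       s2b, s2e, s2o, state)
        full = np.concatenate([theta, s2b, s2e, [] if s2o is None else [s2o]])
        floors = np.concatenate([g_floor, np.full(len(full) - structure.n_params, var_floor)])
        # active set: variance parameters pinned at their floor with a score
        # pointing further down are frozen for this iteration
        frozen = (full <= floors * (1 + 1e-10)) & (score < 0)
        free = ~frozen
        # AI step with ridge for safety
        d = np.sqrt(np.maximum(np.diag(AI), 1e-12))
        AIr = AI + options.ai_ridge * np.outer(d, d) + 1e-12 * np.eye(len(score))
        delta = np.zeros_like(full)
        try:
            delta[free] = np.linalg.solve(AIr[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            delta[free] = score[free] / np.maximum(np.diag(AIr)[free], 1e-8)
        # trust region: near-singular AI matrices can propose enormous steps
        # in flat directions that step-halving alone cannot recover from
        ref = np.maximum(np.abs(full), 1e-2 * np.sqrt(vbar))
        ratio = float(np.max(np.abs(delta) / ref))
        if ratio > 50.0:
            delta = delta * (50.0 / ratio)

        def _try_direction(direction):
            stepsize = 1.0
            for _ in range(options.max_halvings + 1):
                cand = full + stepsize * direction
                cand = _apply_floors(cand, structure, g_floor, var_floor, design)
                th_c = cand[:structure.n_params]
                s2b_c = cand[structure.n_params:structure.n_params + p]
                s2e_c = cand[structure.n_params + p:structure.n_params + 2 * p]
                s2o_c = cand[-1] if s2o is not None else None
                st_c = _evaluate(design, structure, Gg_inv, logdet_Gg,
                                 th_c, s2b_c, s2e_c, s2o_c)
                if st_c.ok and st_c.m2ll <= state.m2ll + 1e-10:
                    return cand, st_c
                stepsize *= 0.5
            return None

        best = _try_direction(delta)
        if best is None:
            # fall back to a diagonally preconditioned gradient step
            jacobi = np.zeros_like(full)
            jacobi[free] = score[free] / np.maximum(np.diag(AIr)[free], 1e-8)
            ratio = float(np.max(np.abs(jacobi) / ref))
            if ratio > 10.0:
                jacobi = jacobi * (10.0 / ratio)
            best = _try_direction(jacobi)
        if best is None:
            # no improving step in any tried direction: local stationarity
            converged = True
            break
        cand, st_c = best
        rel = np.max(np.abs(cand - full) / np.maximum(np.abs(full), 1e-8 * vbar))
        rel_ll = abs(st_c.m2ll - state.m2ll) / max(abs(state.m2ll), 1.0)
        theta = cand[:structure.n_params]
        s2b = cand[structure.n_params:structure.n_params + p]
        s2e = cand[structure.n_params + p:structure.n_params + 2 * p]
        if s2o is not None:
            s2o = cand[-1]
        state = st_c
        trace.append(-0.5 * state.m2ll)
        if options.verbose:
            print(f"iter {it}: loglik {-0.5 * state.m2ll:.6f} rel {rel:.2e}")
        if rel < options.tol_param and rel_ll < options.tol_loglik:
            converged = True
            break

    return _finalise(dataset, design, spec, structure, basis, theta, s2b, s2e, s2o,
                     state, Gg, Gg_inv, ridge, converged, n_iter, trace)


def _apply_floors(cand, structure, g_floor, var_floor, design):
    cand = cand.copy()
    ng = structure.n_params
    cand[:ng] = np.maximum(cand[:ng], g_floor)
    cand[ng:] = np.maximum(cand[ng:], var_floor)
    return cand


def _score_and_ai(design, structure, Gg, Gg_inv, theta, s2b, s2e, s2o, state):
    """REML score vector and average-information matrix at the current point."""
    p, v, nb = design.p, design.v, design.nb
    o = design.off_u
    c = state.chol
    dsc = state.dscale
    sol = state.sol

    Umat = sol[:p * v].reshape(p, v).T                 # v x p BLUPs of cells
    Wmat = Gg_inv @ Umat @ state.Ge_inv                # w = G^-1 u_hat
    GgW = Gg @ Wmat
    Omega = Wmat.T @ GgW                               # quadratic-form kernel

    derivs = structure.ge_derivs(theta)
    ngen = len(derivs)
    Dstack = np.stack(derivs)

    # residuals and random-effect solutions at plot level
    resid = design.y - design.W @ sol
    rinv_plot = 1.0 / s2e[design.env]
    ub = sol[design.off_b:design.off_b + nb]

    # --- AI matrix from working variates (needs the factor, not the inverse)
    npar = ngen + 2 * p + (1 if s2o is not None else 0)
    Ydot = np.zeros((design.n, npar))
    for i in range(ngen):
        Gm = GgW @ Dstack[i].T                         # v x p
        Ydot[:, i] = Gm[design.gen, design.env]
    for j in range(p):
        selp = design.env == j
        Ydot[selp, ngen + j] = ub[design.block[selp]] / s2b[j]
        Ydot[selp, ngen + p + j] = resid[selp] / s2e[j]
    if s2o is not None:
        uo = sol[design.off_o:design.off_o + p]
        Ydot[:, -1] = uo[design.env] / s2o

    RY = Ydot * rinv_plot[:, None]
    T = design.W.T @ RY
    sol2, info = dpotrs(c, T / dsc[:, None], lower=1)
    sol2 = sol2 / dsc[:, None]
    PY = RY - (design.W @ sol2) * rinv_plot[:, None]
    AI = 0.5 * (Ydot.T @ PY)
    AI = 0.5 * (AI + AI.T)

    # --- score vector (trace terms need the inverse; invert in place) ------
    # dpotri fills the lower triangle only; the upper triangle holds stale
    # factor data, so every read below stays in the lower triangle
    Cinv, info = dpotri(c, lower=1, overwrite_c=1)
    if info != 0:
        raise RemlError("failed to invert the mixed-model coefficient matrix")
    Cinv /= dsc[:, None]
    Cinv /= dsc[None, :]
    state.chol = None                                  # factor consumed

    # H2[a,b] = tr(Cuu[a,b] @ Gg_inv), using C^uu[a,b] = C^uu[b,a]' and the
    # symmetry of Gg_inv to read only lower-triangle blocks
    H2 = np.empty((p, p))
    for a in range(p):
        ra = slice(o + a * v, o + (a + 1) * v)
        diag_blk = Cinv[ra, ra]
        H2[a, a] = 2.0 * float(np.sum(np.tril(diag_blk, -1) * Gg_inv)) \
            + float(np.diag(diag_blk) @ np.diag(Gg_inv))
        for b in range(a + 1, p):
            rb = slice(o + b * v, o + (b + 1) * v)
            H2[a, b] = H2[b, a] = float(np.sum(Cinv[rb, ra] * Gg_inv))
    tau_tr = v * state.Ge_inv - state.Ge_inv @ H2 @ state.Ge_inv
    s_gen = -0.5 * (np.tensordot(Dstack, tau_tr, axes=2) - np.tensordot(Dstack, Omega, axes=2))

    # block-variance scores
    diagC_b = np.diag(Cinv)[design.off_b:design.off_b + nb]
    s_blk = np.zeros(p)
    for j in range(p):
        selb = design.block_env == j
        tr_term = design.nb_j[j] / s2b[j] - diagC_b[selb].sum() / s2b[j] ** 2
        quad = float(np.sum(ub[selb] ** 2)) / s2b[j] ** 2
        s_blk[j] = -0.5 * (tr_term - quad)

    # residual-variance scores
    s_res = np.zeros(p)
    for j in range(p):
        gj = design.gram[j]
        trj = float(np.sum(gj.data * Cinv[design.gram_lo[j]]))
        selp = design.env == j
        ssr = float(np.sum(resid[selp] ** 2))
        tr_term = design.n_j[j] / s2e[j] - trj / s2e[j] ** 2
        s_res[j] = -0.5 * (tr_term - ssr / s2e[j] ** 2)

    score = [s_gen, s_blk, s_res]
    if s2o is not None:
        io = slice(design.off_o, design.off_o + p)
        uo = sol[io]
        tr_term = p / s2o - float(np.trace(Cinv[io, io])) / s2o ** 2
        score.append(np.array([-0.5 * (tr_term - float(uo @ uo) / s2o ** 2)]))
    score = np.concatenate(score)
    return score, AI, {"Wmat": Wmat, "GgW": GgW, "resid": resid}


def _finalise(dataset, design, spec, structure, basis, theta, s2b, s2e, s2o,
              state, Gg, Gg_inv, ridge, converged, n_iter, trace) -> FittedModel:
    p, v = design.p, design.v
    sol = state.sol
    Umat = sol[:p * v].reshape(p, v).T
    Wmat = Gg_inv @ Umat @ state.Ge_inv
    GgW = Gg @ Wmat
    params = structure.unpack(theta)
    params.d = np.ones(spec.k) if spec.family in ("FA", "FAM", "FAR", "IFA") else None

    f_star = delta = gamma1 = None
    if spec.family in ("FA", "FAM", "FAR", "IFA"):
        from .variance import composite_loadings
        lam_env = composite_loadings(params, basis, p)
        f_star = GgW @ lam_env
        delta = GgW * params.psi                       # v x p, psi_j Gg w_j
        if spec.family == "FAM":
            gamma1 = params.sigma2_1 * np.sqrt(p) * GgW.sum(axis=1)

    n_gen = structure.n_params
    n_total = n_gen + 2 * p + (1 if s2o is not None else 0)
    return FittedModel(
        spec=spec, params=params, Ge=state.Ge,
        sigma2_block=s2b.copy(), sigma2_resid=s2e.copy(),
        sigma2_omega=s2o,
        tau=sol[design.off_x:design.off_x + design.px].copy(),
        loglik=-0.5 * state.m2ll,
        n_params_genetic=n_gen, n_params_total=n_total,
        converged=converged, n_iter=n_iter, trace=trace,
        w=Wmat, gg_w=GgW, u_hat=Umat,
        f_star=f_star, delta=delta, gamma1=gamma1,
        basis=basis, grm_ridge_used=ridge,
        env_levels=list(dataset.env_levels),
        genotype_levels=list(dataset.genotype_levels),
    )


def loglik_at(
    dataset: METDataset,
    grm: GenomicRelationship,
    basis: CovariateBasis | None,
    spec: VarianceModelSpec,
    params: GeParameters,
    sigma2_block: np.ndarray,
    sigma2_resid: np.ndarray,
    options: FitOptions | None = None,
) -> float:
    """Residual log-likelihood at given parameter values (no optimisation)."""
    options = options or FitOptions()
    grm = grm.reorder(dataset.genotype_levels)
    design = _Design(dataset, options, basis)
    ridge = options.grm_ridge
    if ridge is None:
        ridge = 1e-5 * float(np.mean(np.diag(grm.G)))
    Gg = grm.G + ridge * np.eye(design.v)
    logdet_Gg, Gg_inv = _safe_chol_inv(Gg, "G_g")
    structure = GeStructure(spec, design.p, basis)
    theta = structure.pack(params)
    st = _evaluate(design, structure, Gg_inv, logdet_Gg, theta,
                   np.asarray(sigma2_block, float), np.asarray(sigma2_resid, float), None)
    if not st.ok:
        raise RemlError("likelihood evaluation failed at the given parameters")
    return -0.5 * st.m2ll
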