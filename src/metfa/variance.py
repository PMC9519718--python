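"""Variance models for the between-environment genetic covariance matrix G_e.

Each model family describes the p x p additive genetic covariance between
environments, with var(u) = G_e (x) G_g for the vp-vector of genotype-by-
environment (GE) effects:

====== =====================================================================
id     sigma2_ge * I_p
diag   diag(sigma2_ge_j)
comp   sigma2_g * J_p + sigma2_ge * I_p
mdiag  sigma2_g * J_p + diag(sigma2_ge_j)
FAMk   sigma2_1 * J_p + Lambda D Lambda' + Psi   (explicit genotype intercepts)
FAk    Lambda D Lambda' + Psi                    (latent factors only)
rreg1  sigma2_g * J_p + sigma2_s * S S' + Psi    (one slope variance)
rreg2  sigma2_g * J_p + S Sigma_s S' + Psi       (per-covariate slope variances)
FARk   A Lambda_a D Lambda_a' A' + Psi,  A = [1_p/sqrt(p)  S]
IFAk   B Lambda_b D Lambda_b' B' + Psi,  B = [S  Gamma],  S' Gamma = 0
====== =====================================================================

S holds q known environmental covariates (centred, unit length); Gamma spans
(a subspace of) the orthogonal complement of col(S), so the IFA factors are
joint linear combinations of known and latent environmental covariates.  The
IFA family allows fewer latent than known factor columns (k_r < k): latent
loading columns beyond k_r are structurally zero.

During REML estimation the score covariance D is fixed at I_k and the upper
right triangle of the (stacked) loadings is constrained to zero; rotation to
the principal-axis form with decreasing d_l is a separate post-fit step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FAMILIES = ("id", "diag", "comp", "mdiag", "FAM", "FA", "rreg1", "rreg2", "FAR", "IFA")
FACTOR_FAMILIES = ("FAM", "FA", "FAR", "IFA")
KNOWN_COVARIATE_FAMILIES = ("rreg1", "rreg2", "FAR", "IFA")

PSI_FLOOR = 1e-8


class ModelSpecError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceModelSpec:
    """Declarative description of one G_e structure.

    ``k`` is the total number of factors; ``k_r`` (IFA only) the number of
    latent factor columns, defaulting to ``k``; ``q`` the number of known
    covariates required by the family (0 for latent-only families).
    """

    family: str
    k: int = 0
    k_r: int | None = None
    q: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ModelSpecError(f"unknown family {self.family!r}")
        if self.family in FACTOR_FAMILIES and self.k < 1:
            raise ModelSpecError(f"{self.family} requires k >= 1")
        if self.family == "IFA":
            kr = self.k if self.k_r is None else self.k_r
            if not 1 <= kr <= self.k:
                raise ModelSpecError("IFA requires 1 <= k_r <= k")
        elif self.k_r is not None:
            raise ModelSpecError("k_r is only meaningful for the IFA family")

    @property
    def kr(self) -> int:
        return (self.k if self.k_r is None else self.k_r) if self.family == "IFA" else self.k

    @property
    def label(self) -> str:
        if self.family == "IFA" and self.kr != self.k:
            return f"IFA{self.k}-{self.kr}"
        if self.family in FACTOR_FAMILIES:
            return f"{self.family}{self.k}"
        return self.family

    def validate(self, p: int, q: int | None = None) -> None:
        q = self.q if q is None else q
        if self.family in KNOWN_COVARIATE_FAMILIES and not q:
            raise ModelSpecError(f"{self.label} requires a known-covariate count q")
        if self.family in ("FA", "FAM") and self.k > p:
            raise ModelSpecError(f"{self.label}: k must not exceed p={p}")
        if self.family == "FAR" and self.k > q + 1:
            raise ModelSpecError(f"{self.label}: FAR requires k <= q+1")
        if self.family == "IFA":
            if q >= p:
                raise ModelSpecError("IFA requires q < p")
            if self.k > p:
                raise ModelSpecError(f"{self.label}: k must not exceed p={p}")
        if self.family in KNOWN_COVARIATE_FAMILIES and q is not None and q >= p:
            raise ModelSpecError("known-covariate families require q < p")


def count_parameters(spec: VarianceModelSpec, p: int, q: int | None = None) -> int:
    """Number of estimated genetic variance parameters for ``spec`` at (p, q).

    Closed forms per family; the IFA count with k_r < k reflects the latent
    loading columns beyond k_r being structurally zero:
    ``q k + (p - q) k_r - k(k-1)/2 + p``.
    """
    q = spec.q if q is None else q
    spec.validate(p, q)
    k = spec.k
    if spec.family == "id":
        return 1
    if spec.family == "diag":
        return p
    if spec.family == "comp":
        return 2
    if spec.family == "mdiag":
        return p + 1
    if spec.family == "FAM":
        return p * (k + 1) - k * (k - 1) // 2 + 1
    if spec.family == "FA":
        return p * (k + 1) - k * (k - 1) // 2
    if spec.family == "rreg1":
        return p + 2
    if spec.family == "rreg2":
        return p + q + 1
    if spec.family == "FAR":
        return p + k * (2 * q - k + 3) // 2
    if spec.family == "IFA":
        return q * k + (p - q) * spec.kr - k * (k - 1) // 2 + p
    raise ModelSpecError(spec.family)


# ---------------------------------------------------------------------------
# covariate basis


@dataclass
class CovariateBasis:
    """Basis matrices for known-covariate regressions.

    ``S`` (p x q) holds the known covariates, ``Gamma`` (p x g, g <= p - q)
    an orthonormal basis of (a subspace of) the orthogonal complement of
    col(S), ``B = [S Gamma]`` and ``A = [1_p/sqrt(p)  S]``.
    """

    S: np.ndarray
    Gamma: np.ndarray

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @property
    def q(self) -> int:
        return self.S.shape[1]

    @property
    def g(self) -> int:
        return self.Gamma.shape[1]

    @property
    def B(self) -> np.ndarray:
        return np.hstack([self.S, self.Gamma])

    @property
    def A(self) -> np.ndarray:
        p = self.p
        return np.hstack([np.full((p, 1), 1.0 / np.sqrt(p)), self.S])


def build_projection(S: np.ndarray, n_latent_columns: int | None = None) -> CovariateBasis:
    """Construct Gamma from the orthogonal-complement projector of S.

    Takes the first (p - q) columns of ``I - S (S'S)^-1 S'`` and
    orthonormalises them by QR (span unchanged, verified against the
    projector), then keeps the leading ``n_latent_columns`` of them.
    Deterministic for fixed S.
    """
    S = np.asarray(S, dtype=float)
    p, q = S.shape
    if q >= p:
        raise ModelSpecError(f"projection requires q < p; got q={q}, p={p}")
    g = p - q if n_latent_columns is None else int(n_latent_columns)
    if not 1 <= g <= p - q:
        raise ModelSpecError(f"n_latent_columns must lie in [1, {p - q}]")
    cond = np.linalg.cond(S)
    if cond > 1e10:
        raise ModelSpecError(f"covariate matrix numerically rank deficient (cond={cond:.3g})")
    P = np.eye(p) - S @ np.linalg.solve(S.T @ S, S.T)
    cols = P[:, : p - q]
    Q, R = np.linalg.qr(cols)
    # deterministic signs: positive diagonal of R
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    if np.max(np.abs(P @ Q - Q)) > 1e-8:
        raise ModelSpecError("orthogonal-complement columns do not span the projector range")
    basis = CovariateBasis(S=S, Gamma=Q[:, :g])
    if np.max(np.abs(S.T @ basis.Gamma)) > 1e-10:
        raise ModelSpecError("S' Gamma != 0 after projection")
    return basis


# ---------------------------------------------------------------------------
# parameter containers and assembly


@dataclass
class GeParameters:
    """Family-dependent parameters of one G_e structure.

    Only the fields a family uses are populated; ``d`` defaults to ones
    (the estimation constraint D = I_k).
    """

    spec: VarianceModelSpec
    variances: np.ndarray | None = None       # id/diag/comp/mdiag/rreg scalar blocks
    loadings: np.ndarray | None = None        # stacked loadings (rows in family basis)
    d: np.ndarray | None = None               # score variances, len k
    psi: np.ndarray | None = None             # specific variances, len p
    sigma2_1: float | None = None             # FAM intercept variance

    def copy(self) -> "GeParameters":
        return GeParameters(
            self.spec,
            None if self.variances is None else self.variances.copy(),
            None if self.loadings is None else self.loadings.copy(),
            None if self.d is None else self.d.copy(),
            None if self.psi is None else self.psi.copy(),
            self.sigma2_1,
        )


def _check_nonneg(x, what):
    if np.any(np.asarray(x) < 0):
        raise ModelSpecError(f"negative {what} in G_e parameters")


def composite_loadings(params: GeParameters, basis: CovariateBasis | None, p: int) -> np.ndarray:
    """The p x k environment loadings Phi @ Lambda in environment space."""
    spec = params.spec
    L = params.loadings
    if spec.family in ("FA", "FAM"):
        return L
    if spec.family == "FAR":
        return basis.A @ L
    if spec.family == "IFA":
        return basis.B @ L
    raise ModelSpecError(f"{spec.family} has no factor loadings")


def assemble_Ge(
    params: GeParameters,
    basis: CovariateBasis | None = None,
    p: int | None = None,
) -> np.ndarray:
    """Assemble the p x p matrix G_e from a parameter set."""
    spec = params.spec
    fam = spec.family
    if fam in ("id", "diag", "comp", "mdiag"):
        v = np.asarray(params.variances, dtype=float)
        _check_nonneg(v, "variance")
        if fam == "id":
            return v[0] * np.eye(p)
        if fam == "diag":
            return np.diag(v)
        if fam == "comp":
            return v[0] * np.ones((p, p)) + v[1] * np.eye(p)
        return v[0] * np.ones((p, p)) + np.diag(v[1:])
    psi = np.asarray(params.psi, dtype=float)
    _check_nonneg(psi, "specific variance")
    p = len(psi)
    if fam == "rreg1":
        v = params.variances
        _check_nonneg(v, "variance")
        S = basis.S
        return v[0] * np.ones((p, p)) + v[1] * (S @ S.T) + np.diag(psi)
    if fam == "rreg2":
        v = params.variances
        _check_nonneg(v, "variance")
        S = basis.S
        return v[0] * np.ones((p, p)) + S @ np.diag(v[1:]) @ S.T + np.diag(psi)
    d = np.ones(spec.k) if params.d is None else np.asarray(params.d, dtype=float)
    _check_nonneg(d, "score variance")
    Lam = composite_loadings(params, basis, p)
    G = (Lam * d) @ Lam.T + np.diag(psi)
    if fam == "FAM":
        _check_nonneg(params.sigma2_1, "intercept variance")
        G = G + params.sigma2_1 * np.ones((p, p))
    return 0.5 * (G + G.T)


def fam_as_special_fa(params: GeParameters, p: int) -> dict:
    """Re-express FAM parameters as the equivalent special FA(k+1) form.

    Returns the augmented loadings ``[1_p/sqrt(p)  Lambda_star]`` with
    Gram-Schmidt-centred higher-order columns (``Lambda_star' 1_p = 0``), the
    (k+1) x (k+1) score covariance ``D_star`` reproducing the same G_e, and
    the induced simple-main-effect variance
    ``sigma2_g = sigma2_1 + sum_l d_l lambda_bar_l^2``.
    """
    if params.spec.family != "FAM":
        raise ModelSpecError("fam_as_special_fa expects FAM parameters")
    Lam = params.loadings
    d = np.ones(params.spec.k) if params.d is None else params.d
    one_star = np.full((p, 1), 1.0 / np.sqrt(p))
    lam_bar = Lam.mean(axis=0)                       # per-factor mean loadings
    Lam_star = Lam - np.ones((p, 1)) * lam_bar       # centred columns
    k = params.spec.k
    # u = 1* gamma1 + Lam f + delta = 1*(gamma1 + sqrt(p) sum lam_bar_l f_l) + Lam* f + delta
    sigma2_g = params.sigma2_1 + float(np.sum(d * lam_bar**2))
    D = np.zeros((k + 1, k + 1))
    D[0, 0] = p * sigma2_g
    D[0, 1:] = D[1:, 0] = np.sqrt(p) * lam_bar * d
    D[1:, 1:] = np.diag(d)
    aug = np.hstack([one_star, Lam_star])
    return {
        "loadings": aug,
        "D": D,
        "sigma2_g": sigma2_g,
        "lam_bar": lam_bar,
        "Ge": aug @ D @ aug.T + np.diag(params.psi),
    }


# ---------------------------------------------------------------------------
# estimation-scale parameterisation (D = I_k, upper-right loadings zero)
#
# The REML engine works with a flat vector theta of free genetic parameters.
# The helpers below define the packing, assemble G_e(theta) and return the
# analytic derivative dG_e/dtheta_i for every free parameter.


def _loading_free_entries(rows: int, k: int, kr: int, known_rows: int | None = None) -> list[tuple[int, int]]:
    """(row, col) of free entries in the stacked loadings under the constraints.

    Upper-right triangle zero (row < col in stacked order); for IFA with
    reduced latent rank, latent rows (beyond ``known_rows``) have zero
    entries in columns >= kr.
    """
    free = []
    for c in range(k):
        for r in range(rows):
            if r < c:
                continue
            if known_rows is not None and r >= known_rows and c >= kr:
                continue
            free.append((r, c))
    return free


class GeStructure:
    """Estimation-scale view of one family: packing, G_e and derivatives.

    ``basis_matrix`` maps stacked loadings rows to environment space
    (I_p for FA/FAM, A for FAR, B for IFA); rank-one "J_p" terms and
    diagonal variance blocks are handled per family.
    """

    def __init__(self, spec: VarianceModelSpec, p: int, basis: CovariateBasis | None):
        spec.validate(p, basis.q if basis is not None else None)
        self.spec = spec
        self.p = p
        self.basis = basis
        fam = spec.family
        if fam in KNOWN_COVARIATE_FAMILIES and basis is None:
            raise ModelSpecError(f"{fam} requires a covariate basis")
        self.has_psi = fam not in ("id", "diag", "comp", "mdiag")
        if fam in ("FA", "FAM"):
            self.Phi = np.eye(p)
            self.load_rows = p
            self.free = _loading_free_entries(p, spec.k, spec.k)
        elif fam == "FAR":
            self.Phi = basis.A
            self.load_rows = basis.q + 1
            self.free = _loading_free_entries(self.load_rows, spec.k, spec.k)
        elif fam == "IFA":
            self.Phi = basis.B
            self.load_rows = basis.q + basis.g
            self.free = _loading_free_entries(self.load_rows, spec.k, spec.kr, known_rows=basis.q)
        else:
            self.Phi = None
            self.load_rows = 0
            self.free = []
        self.n_var = {"id": 1, "diag": p, "comp": 2, "mdiag": p + 1,
                      "rreg1": 2, "rreg2": 1 + (basis.q if basis else 0)}.get(fam, 0)
        self.n_sigma1 = 1 if fam == "FAM" else 0
        self.n_load = len(self.free)
        self.n_psi = p if self.has_psi else 0
        self.n_params = self.n_var + self.n_sigma1 + self.n_load + self.n_psi
        if fam in KNOWN_COVARIATE_FAMILIES or fam in ("id", "diag", "comp", "mdiag"):
            expected = count_parameters(spec, p, basis.q if basis is not None else None)
        else:
            expected = count_parameters(spec, p)
        assert self.n_params == expected, (self.n_params, expected)

    # -- packing ------------------------------------------------------------

    def pack(self, params: GeParameters) -> np.ndarray:
        theta = []
        if self.n_var:
            theta.extend(np.asarray(params.variances, dtype=float))
        if self.n_sigma1:
            theta.append(float(params.sigma2_1))
        if self.n_load:
            L = params.loadings
            theta.extend(L[r, c] for r, c in self.free)
        if self.n_psi:
            theta.extend(np.asarray(params.psi, dtype=float))
        out = np.asarray(theta, dtype=float)
        assert out.size == self.n_params
        return out

    def unpack(self, theta: np.ndarray) -> GeParameters:
        theta = np.asarray(theta, dtype=float)
        i = 0
        variances = loadings = psi = None
        sigma2_1 = None
        if self.n_var:
            variances = theta[i:i + self.n_var].copy()
            i += self.n_var
        if self.n_sigma1:
            sigma2_1 = float(theta[i]); i += 1
        if self.n_load:
            loadings = np.zeros((self.load_rows, self.spec.k))
            for (r, c), val in zip(self.free, theta[i:i + self.n_load]):
                loadings[r, c] = val
            i += self.n_load
        if self.n_psi:
            psi = theta[i:i + self.n_psi].copy()
            i += self.n_psi
        return GeParameters(self.spec, variances, loadings, None, psi, sigma2_1)

    def variance_mask(self) -> np.ndarray:
        """True for parameters constrained to be non-negative."""
        mask = np.zeros(self.n_params, dtype=bool)
        mask[: self.n_var + self.n_sigma1] = True
        if self.n_psi:
            mask[-self.n_psi:] = True
        return mask

    # -- G_e and derivatives -----------------------------------------------

    def ge(self, theta: np.ndarray) -> np.ndarray:
        params = self.unpack(theta)
        params.d = None  # estimation scale: D = I
        return assemble_Ge(params, self.basis, self.p)

    def ge_derivs(self, theta: np.ndarray) -> list[np.ndarray]:
        """dG_e/dtheta_i for every free parameter, as dense p x p matrices."""
        p = self.p
        fam = self.spec.family
        params = self.unpack(theta)
        derivs: list[np.ndarray] = []
        J = np.ones((p, p))
        if fam == "id":
            derivs.append(np.eye(p))
        elif fam == "diag":
            derivs.extend(np.diag(e) for e in np.eye(p))
        elif fam == "comp":
            derivs.extend([J, np.eye(p)])
        elif fam == "mdiag":
            derivs.append(J)
            derivs.extend(np.diag(e) for e in np.eye(p))
        elif fam == "rreg1":
            S = self.basis.S
            derivs.extend([J, S @ S.T])
        elif fam == "rreg2":
            S = self.basis.S
            derivs.append(J)
            derivs.extend(np.outer(S[:, i], S[:, i]) for i in range(S.shape[1]))
        elif fam in ("FA", "FAM", "FAR", "IFA"):
            if fam == "FAM":
                derivs.append(J)
        else:  # pragma: no cover
            raise ModelSpecError(fam)
        if self.n_load:
            Lam_env = self.Phi @ params.loadings          # p x k composite loadings
            for r, c in self.free:
                col = self.Phi[:, r]
                D = np.outer(col, Lam_env[:, c])
                derivs.append(D + D.T)
        if self.n_psi:
            derivs.extend(np.diag(e) for e in np.eye(p))
        assert len(derivs) == self.n_params
        return derivs

    def parameter_names(self) -> list[str]:
        fam = self.spec.family
        names = []
        if fam == "id":
            names.append("sigma2_ge")
        elif fam == "diag":
            names.extend(f"sigma2_ge[{j}]" for j in range(self.p))
        elif fam == "comp":
            names.extend(["sigma2_g", "sigma2_ge"])
        elif fam == "mdiag":
            names.append("sigma2_g")
            names.extend(f"sigma2_ge[{j}]" for j in range(self.p))
        elif fam == "rreg1":
            names.extend(["sigma2_g", "sigma2_s"])
        elif fam == "rreg2":
            names.append("sigma2_g")
            names.extend(f"sigma2_s[{i}]" for i in range(self.basis.q))
        if self.n_sigma1:
            names.append("sigma2_1")
        names.extend(f"lambda[{r},{c}]" for r, c in self.free)
        if self.n_psi:
            names.extend(f"psi[{j}]" for j in range(self.p))
        return names
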