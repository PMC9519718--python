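"""Rotation of constrained factor solutions to principal axes.

REML estimation fixes the score covariance at I_k and zeroes the upper-right
triangle of the loadings.  For interpretation the loadings and scores are
rotated back so that the composite environment loadings are orthonormal
(``Lambda' Lambda = I_k``), the score variances ``d_1 > d_2 > ... > d_k``
are the squared singular values of the constrained composite loadings, and
the first factor points "up" (positive mean loading).  The rotation is a
singular value decomposition

    B Lambda* = U D^{1/2} V',

after which ``Lambda = U``, ``Lambda_b = B^+ U`` and
``f = f* V D^{1/2}``.  G_e and all fitted GE effects are unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reml import FittedModel
from .variance import CovariateBasis, ModelSpecError, VarianceModelSpec


class RotationError(ValueError):
    pass


@dataclass
class RotatedSolution:
    """Principal-axis loadings, score variances and rotated scores."""

    spec: VarianceModelSpec
    lambda_env: np.ndarray          # p x k orthonormal composite loadings (U)
    lambda_basis: np.ndarray        # loadings in the family basis rows (B^+ U)
    d: np.ndarray                   # score variances, strictly decreasing
    scores: np.ndarray              # v x k rotated EBLUP scores
    psi: np.ndarray                 # specific variances
    sigma2_1: float | None          # FAM intercept variance
    gamma1: np.ndarray | None       # FAM intercept EBLUPs
    delta: np.ndarray | None        # v x p deviation EBLUPs
    V: np.ndarray                   # right singular vectors of the rotation
    basis: CovariateBasis | None
    Ge: np.ndarray
    env_levels: list = field(default_factory=list)
    genotype_levels: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.lambda_env.shape[1]

    @property
    def p(self) -> int:
        return self.lambda_env.shape[0]

    # family-specific views of the basis loadings ---------------------------

    @property
    def lambda_s(self) -> np.ndarray:
        """Known-covariate loading block (q x k), FAR/IFA families."""
        fam = self.spec.family
        if fam == "IFA":
            return self.lambda_basis[: self.basis.q]
        if fam == "FAR":
            return self.lambda_basis[1: 1 + self.basis.q]
        raise ModelSpecError(f"{fam} has no known-covariate loadings")

    @property
    def lambda_r(self) -> np.ndarray:
        """Latent loading block ((p - q) x k), IFA family."""
        if self.spec.family != "IFA":
            raise ModelSpecError(f"{self.spec.family} has no latent loading block")
        return self.lambda_basis[self.basis.q:]

    @property
    def lambda_g(self) -> np.ndarray:
        """Main-effect loading row (k,), FAR family."""
        if self.spec.family != "FAR":
            raise ModelSpecError("lambda_g is defined for the FAR family")
        return self.lambda_basis[0]

    def common_Ge(self) -> np.ndarray:
        """The common-factor part Lambda D Lambda' of G_e."""
        return (self.lambda_env * self.d) @ self.lambda_env.T


def _family_matrix(spec: VarianceModelSpec, basis: CovariateBasis | None, p: int) -> np.ndarray:
    if spec.family in ("FA", "FAM"):
        return np.eye(p)
    if spec.family == "FAR":
        return basis.A
    if spec.family == "IFA":
        return basis.B
    raise ModelSpecError(f"{spec.family} is not a factor family")


def rotate_loadings(
    loadings_star: np.ndarray,
    scores_star: np.ndarray,
    basis_matrix: np.ndarray,
    collapse_tol: float = 1e-10,
) -> dict:
    """Rotate constrained loadings/scores to the principal-axis form.

    Returns the orthonormal composite loadings ``U`` (p x k), basis-row
    loadings ``B^+ U``, score variances ``d`` (squared singular values,
    decreasing), rotated scores and the right singular vectors ``V``.
    A numerically collapsed factor (singular value ~ 0) is rejected.
    """
    M = basis_matrix @ loadings_star
    U, sv, Vt = np.linalg.svd(M, full_matrices=False)
    k = loadings_star.shape[1]
    if sv[0] <= 0:
        raise RotationError("all factors collapsed (zero loadings)")
    collapsed = np.flatnonzero(sv < np.sqrt(collapse_tol) * sv[0])
    if len(collapsed):
        raise RotationError(f"collapsed factor index {int(collapsed[0])}: "
                            "loadings are rank deficient")
    V = Vt.T
    d = sv**2
    lambda_basis = np.linalg.lstsq(basis_matrix, U, rcond=None)[0]
    scores = scores_star @ V * sv
    return {"lambda_env": U, "lambda_basis": lambda_basis, "d": d,
            "scores": scores, "V": V}


def rotate(fit: FittedModel, apply_signs: bool = True) -> RotatedSolution:
    """Rotate a fitted factor model to principal axes.

    The rotation leaves G_e and all fitted GE effects unchanged; by default
    the sign convention (positive first factor) is applied afterwards.
    """
    spec = fit.spec
    if spec.family not in ("FA", "FAM", "FAR", "IFA"):
        raise ModelSpecError(f"{spec.family} has no factors to rotate")
    Phi = _family_matrix(spec, fit.basis, fit.p)
    out = rotate_loadings(fit.params.loadings, fit.f_star, Phi)
    rot = RotatedSolution(
        spec=spec,
        lambda_env=out["lambda_env"],
        lambda_basis=out["lambda_basis"],
        d=out["d"],
        scores=out["scores"],
        psi=fit.params.psi.copy(),
        sigma2_1=fit.params.sigma2_1,
        gamma1=None if fit.gamma1 is None else fit.gamma1.copy(),
        delta=None if fit.delta is None else fit.delta.copy(),
        V=out["V"],
        basis=fit.basis,
        Ge=fit.Ge.copy(),
        env_levels=list(fit.env_levels),
        genotype_levels=list(fit.genotype_levels),
    )
    return sign_convention(rot) if apply_signs else rot


def sign_convention(rot: RotatedSolution) -> RotatedSolution:
    """Orient factors: positive first factor, non-negative mean thereafter.

    The first factor is flipped so the mean composite loading is positive
    (a warning lists environments that remain negative); higher factors are
    flipped so their mean loading is non-negative, with exact zeros left
    unchanged.  Scores flip in tandem so fitted GE effects are unchanged.
    """
    L = rot.lambda_env.copy()
    Lb = rot.lambda_basis.copy()
    F = rot.scores.copy()
    for l in range(rot.k):
        m = L[:, l].mean()
        if (m < 0) if l > 0 else (m < 0 or (m == 0 and L[:, l].min() < 0)):
            L[:, l] *= -1
            Lb[:, l] *= -1
            F[:, l] *= -1
    neg = np.flatnonzero(L[:, 0] < 0)
    if len(neg) and len(neg) < rot.p:
        envs = [rot.env_levels[j] for j in neg] if rot.env_levels else neg.tolist()
        warnings.warn(f"first factor has mixed-sign loadings; negative in: {envs}",
                      stacklevel=2)
    return RotatedSolution(
        spec=rot.spec, lambda_env=L, lambda_basis=Lb, d=rot.d.copy(), scores=F,
        psi=rot.psi, sigma2_1=rot.sigma2_1, gamma1=rot.gamma1, delta=rot.delta,
        V=rot.V, basis=rot.basis, Ge=rot.Ge,
        env_levels=rot.env_levels, genotype_levels=rot.genotype_levels,
    )
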