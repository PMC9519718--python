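"""Prediction into current and future environments.

Models whose factors involve known environmental covariates (rreg1, rreg2,
FAR, IFA) can predict GE effects for an environment from its covariates and
the genotypes' estimated scores.  Prediction into *current* environments is
assessed by leave-one-environment-out cross-validation: the model is refit
on the other p-1 environments (covariates re-centred and re-scaled on the
training set, the orthogonal complement rebuilt), the left-out
environment's GE effects are predicted from its covariates, and accuracy is
the correlation with the genotype mean yields actually observed there.
Prediction into *future* environments applies the full-data fit to new
covariates transformed with the stored training centring and scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CovariateMatrix, GenomicRelationship, METDataset, prepare_covariates
from .reml import FitOptions, FittedModel, fit
from .rotation import RotatedSolution, rotate
from .variance import ModelSpecError, VarianceModelSpec, build_projection

PREDICTIVE_FAMILIES = ("rreg1", "rreg2", "FAR", "IFA")


@dataclass
class PredictionResult:
    """Predicted GE effects and accuracy for one environment."""

    env: str
    mode: str                       # "current" | "future"
    genotype_levels: list
    u_pred: np.ndarray              # predicted GE effect per genotype
    y_mean: np.ndarray | None       # observed genotype mean yields (NaN = absent)
    accuracy: float | None          # cor(y_mean, u_pred); None if undefined
    n_genotypes: int
    region: str | None = None


def _genotype_means(dataset: METDataset, env: str) -> np.ndarray:
    """Simple arithmetic means of non-missing plot values per genotype."""
    obs = dataset.observed()
    sub = obs[obs["env"] == env]
    means = np.full(dataset.v, np.nan)
    grp = sub.groupby("genotype_idx")["value"].mean()
    means[grp.index.to_numpy()] = grp.to_numpy()
    return means


def _predict_env(
    fitted: FittedModel,
    rot: RotatedSolution | None,
    s_row: np.ndarray,
    p_train: int,
) -> np.ndarray:
    """Predicted GE effects for one environment from its covariate row.

    Factor families use the rotated loadings and scores:
    ``u = (S_j Lambda_s + lambda_bar_r) f`` for IFA (the latent term enters
    through the mean latent loadings), and the main-effect row for FAR.
    The simpler random regressions use their slope and main-effect EBLUPs.
    """
    fam = fitted.spec.family
    if fam in ("FAR", "IFA"):
        if fam == "IFA":
            lam_bar_r = rot.lambda_r.sum(axis=0) / p_train
            row = s_row @ rot.lambda_s + lam_bar_r
        else:
            row = rot.lambda_g / np.sqrt(p_train) + s_row @ rot.lambda_s
        return rot.scores @ row
    # rreg families: EBLUPs of main effects and slopes from the cell system
    GgW = fitted.gg_w
    S = fitted.basis.S
    v = fitted.params.variances
    gamma_g = v[0] * np.sqrt(p_train) * GgW.sum(axis=1)      # p sigma2_g (1*' (x) Gg) w
    if fam == "rreg1":
        slopes = v[1] * (GgW @ S)                            # v x q
    else:
        slopes = (GgW @ S) * v[1:]
    return gamma_g / np.sqrt(p_train) + slopes @ s_row


def loeo_cv(
    dataset: METDataset,
    grm: GenomicRelationship,
    covariates_raw: pd.DataFrame,
    spec: VarianceModelSpec,
    options: FitOptions | None = None,
    regions: dict | None = None,
    min_genotypes: int = 3,
) -> list[PredictionResult]:
    """Leave-one-environment-out cross-validation.

    For each environment j the model is refit on the remaining p-1
    environments only: covariates are re-prepared (centred/scaled) on the
    training environments, the left-out row is transformed with the stored
    training offsets, and the projection basis is rebuilt.  Scores are
    genotype-level EBLUPs from the training fit, so no data from the
    left-out environment is used.
    """
    if dataset.p < 3:
        raise ModelSpecError("leave-one-environment-out needs p >= 3")
    if spec.family not in PREDICTIVE_FAMILIES:
        raise ModelSpecError(f"{spec.family} cannot predict unobserved environments")
    options = options or FitOptions()
    results = []
    for env in dataset.env_levels:
        train_envs = [e for e in dataset.env_levels if e != env]
        train = dataset.subset_environments(train_envs)
        cov_train = prepare_covariates(covariates_raw, env_levels=train_envs)
        basis = build_projection(cov_train.S)
        s_row = cov_train.transform(
            covariates_raw.loc[[env]] if env in covariates_raw.index
            else covariates_raw[covariates_raw["env"] == env]
        )[0]
        fitted = fit(train, grm, basis, spec, options)
        rot = rotate(fitted) if spec.family in ("FAR", "IFA") else None
        u_pred = _predict_env(fitted, rot, s_row, train.p)
        # map training genotype order back to the full dataset's order
        gmap = {g: i for i, g in enumerate(fitted.genotype_levels)}
        u_full = np.full(dataset.v, np.nan)
        for i, g in enumerate(dataset.genotype_levels):
            if g in gmap:
                u_full[i] = u_pred[gmap[g]]
        y_mean = _genotype_means(dataset, env)
        ok = ~np.isnan(y_mean) & ~np.isnan(u_full)
        acc = None
        if ok.sum() >= min_genotypes and np.std(u_full[ok]) > 0 and np.std(y_mean[ok]) > 0:
            acc = float(np.corrcoef(y_mean[ok], u_full[ok])[0, 1])
        results.append(PredictionResult(
            env=env, mode="current", genotype_levels=list(dataset.genotype_levels),
            u_pred=u_full, y_mean=y_mean, accuracy=acc, n_genotypes=int(ok.sum()),
            region=(regions or {}).get(env),
        ))
    return results


def predict_future(
    fitted: FittedModel,
    covariates: CovariateMatrix,
    new_covariates_raw: pd.DataFrame,
    validation_means: pd.DataFrame | None = None,
    regions: dict | None = None,
    min_genotypes: int = 3,
) -> list[PredictionResult]:
    """Predict GE effects for future environments from their covariates.

    ``covariates`` must be the training-set preparation (its offsets and
    divisors are applied to the new raw covariates); the latent term enters
    through the mean latent loadings with divisor p.  When validation
    genotype means are supplied (environments x columns ``env, genotype,
    mean``), accuracy is their correlation with the predictions.
    """
    if fitted.spec.family not in PREDICTIVE_FAMILIES:
        raise ModelSpecError(f"{fitted.spec.family} cannot predict future environments")
    rot = rotate(fitted) if fitted.spec.family in ("FAR", "IFA") else None
    new = new_covariates_raw.copy()
    if "env" in new.columns:
        new = new.set_index("env")
    S_new = covariates.transform(new)
    results = []
    for r, env in enumerate(new.index.astype(str)):
        u_pred = _predict_env(fitted, rot, S_new[r], fitted.p)
        y_mean = acc = None
        nok = len(u_pred)
        if validation_means is not None:
            sub = validation_means[validation_means["env"].astype(str) == env]
            gmap = {g: i for i, g in enumerate(fitted.genotype_levels)}
            y_mean = np.full(len(fitted.genotype_levels), np.nan)
            for g, m in zip(sub["genotype"].astype(str), sub["mean"]):
                if g in gmap:
                    y_mean[gmap[g]] = m
            ok = ~np.isnan(y_mean)
            nok = int(ok.sum())
            if nok >= min_genotypes and np.std(u_pred[ok]) > 0 and np.std(y_mean[ok]) > 0:
                acc = float(np.corrcoef(y_mean[ok], u_pred[ok])[0, 1])
        results.append(PredictionResult(
            env=env, mode="future", genotype_levels=list(fitted.genotype_levels),
            u_pred=u_pred, y_mean=y_mean, accuracy=acc, n_genotypes=nok,
            region=(regions or {}).get(env),
        ))
    return results


def accuracy_summary(results: list[PredictionResult]) -> pd.DataFrame:
    """Min/mean/max accuracy per region and overall.

    Environments with undefined accuracy are excluded; their count is
    reported in ``n_undefined``.
    """
    rows = []
    groups: dict = {}
    for r in results:
        groups.setdefault(r.region or "all", []).append(r)
    if len(groups) > 1:
        groups["overall"] = list(results)
    for name, rs in groups.items():
        accs = np.array([r.accuracy for r in rs if r.accuracy is not None], dtype=float)
        rows.append({
            "region": name,
            "n_environments": len(rs),
            "n_undefined": sum(r.accuracy is None for r in rs),
            "min": accs.min() if len(accs) else np.nan,
            "mean": accs.mean() if len(accs) else np.nan,
            "max": accs.max() if len(accs) else np.nan,
        })
    return pd.DataFrame(rows)
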