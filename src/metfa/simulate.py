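"""Synthetic multi-environment trial generator.

Emulates the data-generating process the variance models assume: p
environments each with a number of trials and replicate blocks, v genotypes
related through a marker-derived genomic relationship matrix, q known
environmental covariates (centred and scaled downstream), GE effects drawn
from the chosen variance family (factor structure with known + latent
parts, or the simpler regression/compound structures), per-environment
non-genetic block effects and residual variances, and a configurable
missing-plot rate.

Default sizes and rates mirror a late-stage cotton breeding programme:
v=204 genotypes, p=24 environments with 3 trials of 2 replicate blocks,
q=18 covariates, ~6.5% missing plots, per-environment additive genetic
variance around 0.03 (t/ha)^2 with roughly three quarters of it carried by
the common factors, and plot heritability around one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GenomicRelationship,
    METDataset,
    compute_grm,
    filter_markers,
    load_met_dataset,
    prepare_covariates,
    read_marker_table,
)
from .variance import (
    CovariateBasis,
    GeParameters,
    VarianceModelSpec,
    assemble_Ge,
    build_projection,
)


def simulate_markers(
    v: int,
    r: int,
    af_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Biallelic marker codes in {-1, 0, 1} from binomial sampling.

    Each marker draws an allele frequency uniformly from ``af_range``;
    genotype codes are ``Binomial(2, af) - 1``.  Optional missing calls are
    masked uniformly at ``missing_rate``.
    """
    if v < 2 or r < 1:
        raise ValueError("need v >= 2 genotypes and r >= 1 markers")
    rng = np.random.default_rng(seed)
    af = rng.uniform(*af_range, size=r)
    M = rng.binomial(2, af[None, :], size=(v, r)).astype(float) - 1.0
    if missing_rate > 0:
        mask = rng.random((v, r)) < missing_rate
        # keep at least one observed marker per genotype
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, rng.integers(r)] = False
        M[mask] = np.nan
    idx = [f"G{i + 1:04d}" for i in range(v)]
    cols = [f"M{j + 1:05d}" for j in range(r)]
    return pd.DataFrame(M, index=pd.Index(idx, name="genotype"), columns=cols)


def simulate_covariates(
    p: int,
    q: int,
    correlation: float = 0.4,
    seed: int = 0,
    env_names: list[str] | None = None,
) -> pd.DataFrame:
    """Raw (uncentred) correlated environmental covariates.

    Columns share an exchangeable correlation ``correlation`` and carry
    covariate-specific means and scales, mimicking weather/soil summaries;
    centring and scaling to unit length happens downstream.
    """
    if q >= p:
        raise ValueError(f"need q < p; got q={q}, p={p}")
    rng = np.random.default_rng(seed)
    rho = float(correlation)
    C = np.full((q, q), rho) + (1 - rho) * np.eye(q)
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((p, q)) @ L.T
    means = rng.uniform(5.0, 30.0, size=q)
    sds = rng.uniform(1.0, 5.0, size=q)
    X = means + sds * Z
    if env_names is None:
        env_names = [f"E{j + 1:02d}" for j in range(p)]
    cols = [f"cov{i + 1:02d}" for i in range(q)]
    return pd.DataFrame(X, index=pd.Index(env_names, name="env"), columns=cols)


@dataclass
class SimulationTruth:
    """Generating parameters and latent draws behind one simulated dataset."""

    spec: VarianceModelSpec
    Ge: np.ndarray
    Gg: np.ndarray
    lambda_env: np.ndarray | None      # p x k composite loadings
    lambda_s: np.ndarray | None        # q x k known block (FAR/IFA)
    lambda_r: np.ndarray | None        # (p-q) x k latent block (IFA)
    d: np.ndarray | None
    psi: np.ndarray | None
    basis: CovariateBasis | None
    covariates_raw: pd.DataFrame | None
    markers: pd.DataFrame | None
    f: np.ndarray | None               # v x k true scores
    delta: np.ndarray | None           # v x p true deviations
    u: np.ndarray                      # v x p true GE effects
    env_means: np.ndarray
    sigma2_block: np.ndarray
    sigma2_resid: np.ndarray
    seed: int


def _default_d(k: int, tr_target: float, factor_share: float, decay: float) -> np.ndarray:
    raw = decay ** np.arange(k)
    return factor_share * tr_target * raw / raw.sum()


def simulate_met(
    family: str = "IFA",
    k: int = 4,
    k_r: int | None = None,
    v: int = 204,
    p: int = 24,
    q: int = 18,
    n_trials: int = 3,
    n_blocks: int = 2,
    missing_rate: float = 0.0654,
    env_var_genetic: float = 0.03,
    factor_share: float = 0.75,
    factor_decay: float = 0.45,
    known_weight: float = 0.55,
    sigma2_1: float = 0.008,
    sigma2_block: float = 0.005,
    sigma2_resid: float = 0.025,
    env_mean: float = 1.7,
    env_mean_sd: float = 0.4,
    grm: GenomicRelationship | str = "markers",
    n_markers: int = 800,
    covariate_correlation: float = 0.4,
    seed: int = 0,
    structure_seed: int | None = None,
    d: np.ndarray | None = None,
    psi: np.ndarray | None = None,
) -> tuple[METDataset, SimulationTruth]:
    """Simulate a MET dataset with the exact structure of one variance family.

    The per-environment additive genetic variance averages
    ``env_var_genetic``; ``factor_share`` of its total is carried by the k
    common factors with geometrically decaying score variances, the rest by
    specific variances.  ``known_weight`` sets the share of each composite
    loading drawn from the span of the known covariates (FAR/IFA).  Block
    and residual variances and the missing-plot rate apply per environment.
    Fully reproducible for a fixed seed.  When ``structure_seed`` is given,
    the structural draws (markers, covariates, loadings, variances,
    environment means) use it instead of ``seed``, so replicate datasets can
    share one generating truth while redrawing scores, deviations, block
    effects, residuals and the missing-plot mask.
    """
    noise_rng = np.random.default_rng(seed)
    rng = noise_rng if structure_seed is None else np.random.default_rng(structure_seed)
    spec = VarianceModelSpec(family, k=k, k_r=k_r) if family in ("FA", "FAM", "FAR", "IFA") \
        else VarianceModelSpec(family, k=0)
    kr = spec.kr if family == "IFA" else k

    # genomic relationship
    markers = None
    if isinstance(grm, GenomicRelationship):
        G_rel = grm
        if G_rel.v != v:
            raise ValueError("supplied relationship matrix does not match v")
    elif grm == "identity":
        G_rel = GenomicRelationship(np.eye(v), [f"G{i + 1:04d}" for i in range(v)], 0.0)
    elif grm == "markers":
        markers = simulate_markers(v, n_markers, seed=rng.integers(2**31 - 1))
        G_rel = compute_grm(filter_markers(read_marker_table(markers), knn_k=10))
    else:
        raise ValueError("grm must be 'markers', 'identity' or a GenomicRelationship")
    Gg = G_rel.G
    Lg = np.linalg.cholesky(Gg + 1e-8 * np.mean(np.diag(Gg)) * np.eye(v))

    # known covariates and basis
    covariates_raw = basis = None
    needs_S = family in ("rreg1", "rreg2", "FAR", "IFA")
    if needs_S:
        covariates_raw = simulate_covariates(p, q, covariate_correlation,
                                             seed=rng.integers(2**31 - 1))
        S = prepare_covariates(covariates_raw).S
        basis = build_projection(S)

    tr_target = p * env_var_genetic
    lambda_env = lambda_s = lambda_r = None
    f = delta = None
    d_true = psi_true = None

    if family in ("FA", "FAM", "FAR", "IFA"):
        d_true = _default_d(k, tr_target, factor_share, factor_decay) if d is None \
            else np.asarray(d, float)
        psi_true = (1 - factor_share) * tr_target / p * rng.uniform(0.5, 1.5, size=p) \
            if psi is None else np.asarray(psi, float)
        if family in ("FA", "FAM"):
            raw = rng.standard_normal((p, k))
            lambda_env, _ = np.linalg.qr(raw)
        else:
            # draw known and latent parts, mix with the requested weight
            Ls = rng.standard_normal((q, k))
            known = basis.S @ Ls
            known /= np.linalg.norm(known, axis=0)
            if family == "IFA":
                Lr = rng.standard_normal((basis.g, k))
                Lr[:, kr:] = 0.0
                latent = basis.Gamma @ Lr
            else:
                latent = np.zeros((p, k))
            norms = np.linalg.norm(latent, axis=0)
            latent = np.where(norms > 0, latent / np.where(norms > 0, norms, 1.0), latent)
            mix = np.sqrt(known_weight) * known + np.sqrt(1 - known_weight) * latent
            if family == "IFA" and kr < k:
                # keep the latent block confined to the first k_r factors:
                # orthonormalise the latent-free columns first, project them
                # out of the latent-bearing columns, then orthonormalise those
                Qk, _ = np.linalg.qr(mix[:, kr:])
                resid_cols = mix[:, :kr] - Qk @ (Qk.T @ mix[:, :kr])
                Ql, _ = np.linalg.qr(resid_cols)
                lambda_env = np.hstack([Ql, Qk])
            else:
                lambda_env, _ = np.linalg.qr(mix)
        # deterministic orientation: positive mean first-factor loading
        for l in range(k):
            if lambda_env[:, l].mean() < 0:
                lambda_env[:, l] = -lambda_env[:, l]
        if needs_S:
            coeff = np.linalg.lstsq(basis.B if family == "IFA" else basis.B, lambda_env,
                                    rcond=None)[0]
            lambda_s, lambda_r = coeff[:q], coeff[q:]
            if family == "IFA" and kr < k:
                lambda_r[:, kr:] = 0.0
                lambda_env = basis.S @ lambda_s + basis.Gamma @ lambda_r
        f = Lg @ noise_rng.standard_normal((v, k)) * np.sqrt(d_true)
        delta = Lg @ noise_rng.standard_normal((v, p)) * np.sqrt(psi_true)
        u = f @ lambda_env.T + delta
        Ge = (lambda_env * d_true) @ lambda_env.T + np.diag(psi_true)
        if family == "FAM":
            gamma1 = np.sqrt(p * sigma2_1) * (Lg @ noise_rng.standard_normal(v))
            u = u + np.outer(gamma1, np.full(p, 1.0 / np.sqrt(p)))
            Ge = Ge + sigma2_1 * np.ones((p, p))
    else:
        # non-factor families: build G_e directly and draw u ~ MN(0, Ge, Gg)
        if family == "id":
            Ge = env_var_genetic * np.eye(p)
        elif family == "diag":
            Ge = np.diag(env_var_genetic * rng.uniform(0.5, 1.5, size=p))
        elif family == "comp":
            Ge = 0.5 * env_var_genetic * (np.ones((p, p)) + np.eye(p))
        elif family == "mdiag":
            Ge = 0.5 * env_var_genetic * np.ones((p, p)) \
                + np.diag(0.5 * env_var_genetic * rng.uniform(0.5, 1.5, size=p))
        elif family in ("rreg1", "rreg2"):
            S = basis.S
            s2g = 0.4 * env_var_genetic
            psi_true = 0.3 * env_var_genetic * rng.uniform(0.5, 1.5, size=p)
            scale = 0.3 * tr_target / np.trace(S @ S.T)
            if family == "rreg1":
                Ge = s2g * np.ones((p, p)) + scale * S @ S.T + np.diag(psi_true)
            else:
                s2i = scale * rng.uniform(0.5, 1.5, size=q)
                s2i *= 0.3 * tr_target / np.trace((S * s2i) @ S.T)
                Ge = s2g * np.ones((p, p)) + (S * s2i) @ S.T + np.diag(psi_true)
        else:
            raise ValueError(f"unknown family {family!r}")
        Le = np.linalg.cholesky(Ge + 1e-10 * np.eye(p))
        u = Lg @ noise_rng.standard_normal((v, p)) @ Le.T

    # zero total genetic signal requested explicitly via env_var_genetic = 0
    if env_var_genetic == 0:
        u = np.zeros_like(u)
        Ge = np.zeros((p, p))

    env_means = rng.normal(env_mean, env_mean_sd, size=p)
    s2b = np.full(p, sigma2_block)
    s2e = np.full(p, sigma2_resid)

    env_names = [f"E{j + 1:02d}" for j in range(p)]
    gen_names = list(G_rel.genotype_levels)
    rows = []
    for j in range(p):
        for t in range(n_trials):
            for b in range(n_blocks):
                blk_eff = noise_rng.normal(0.0, np.sqrt(s2b[j]))
                e = noise_rng.normal(0.0, np.sqrt(s2e[j]), size=v)
                vals = env_means[j] + u[:, j] + blk_eff + e
                for i in range(v):
                    rows.append((env_names[j], f"T{t + 1}", f"B{b + 1}", gen_names[i], vals[i]))
    plots = pd.DataFrame(rows, columns=["env", "trial", "block", "genotype", "value"])

    if missing_rate > 0:
        mask = noise_rng.random(len(plots)) < missing_rate
        # never silently drop a genotype from every environment or an
        # environment entirely
        for ident, col in (("genotype", gen_names), ("env", env_names)):
            grp = plots.loc[~mask, ident]
            lost = set(col) - set(grp)
            for name in lost:
                cand = np.flatnonzero((plots[ident] == name).to_numpy() & mask)
                mask[cand[0]] = False
        plots.loc[mask, "value"] = np.nan

    dataset = load_met_dataset(plots, env_order=env_names, genotype_order=gen_names)
    truth = SimulationTruth(
        spec=spec, Ge=Ge, Gg=Gg,
        lambda_env=lambda_env, lambda_s=lambda_s, lambda_r=lambda_r,
        d=d_true, psi=psi_true, basis=basis,
        covariates_raw=covariates_raw, markers=markers,
        f=f, delta=delta, u=u,
        env_means=env_means, sigma2_block=s2b, sigma2_resid=s2e,
        seed=seed,
    )
    return dataset, truth


def write_simulation(dataset: METDataset, truth: SimulationTruth, outdir: str) -> dict:
    """Write the three delimited input files (plus truth) for a simulation."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    pheno = dataset.plots[["env", "trial", "block", "genotype", "value"]]
    paths["phenotypes"] = os.path.join(outdir, "phenotypes.csv")
    pheno.to_csv(paths["phenotypes"], index=False)
    if truth.covariates_raw is not None:
        paths["covariates"] = os.path.join(outdir, "covariates.csv")
        truth.covariates_raw.to_csv(paths["covariates"])
    if truth.markers is not None:
        paths["markers"] = os.path.join(outdir, "markers.csv")
        truth.markers.to_csv(paths["markers"])
    summary = {
        "seed": truth.seed,
        "family": truth.spec.family,
        "k": truth.spec.k,
        "trace_Ge": float(np.trace(truth.Ge)),
        "env_means": truth.env_means.tolist(),
        "sigma2_block": truth.sigma2_block.tolist(),
        "sigma2_resid": truth.sigma2_resid.tolist(),
    }
    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(summary, fh, indent=1)
    return paths
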