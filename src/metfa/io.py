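"""Reading, validation and preparation of multi-environment trial (MET) inputs.

Three delimited text tables drive an analysis:

* plot-level phenotypes with columns ``env, trial, block, genotype, value``
  (empty value = missing plot);
* an environment x covariate table of known environmental covariates
  (rows keyed by environment id);
* a genotype x marker table coded -1/0/1 with empty entries for missing calls.

This module turns them into :class:`METDataset`, :class:`CovariateMatrix`,
:class:`MarkerMatrix` and :class:`GenomicRelationship` objects.  Marker
preparation follows the usual genomic-selection pipeline: monomorphic and
low-information markers are removed, missing calls are imputed by a
k-nearest-neighbour rule, columns are mean-centred and the genomic
relationship matrix is formed as ``M M' / m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = ("env", "trial", "block", "genotype", "value")


class METDataError(ValueError):
    """Raised when an input table violates the MET data contract."""


def _levels(series: pd.Series, order: list[str] | None) -> list[str]:
    # first-appearance order unless an explicit order is supplied
    seen = list(dict.fromkeys(series.astype(str)))
    if order is None:
        return seen
    order = [str(x) for x in order]
    missing = set(seen) - set(order)
    if missing:
        raise METDataError(f"declared level order is missing ids: {sorted(missing)}")
    return [x for x in order if x in set(seen)]


@dataclass
class METDataset:
    """Plot-level phenotypes with environment/trial/block/genotype structure.

    ``plots`` retains missing-trait rows (flagged by ``missing``); they are
    excluded from the response vector but kept for plot bookkeeping.
    """

    plots: pd.DataFrame
    env_levels: list[str]
    genotype_levels: list[str]
    trial_levels: list[str]           # env:trial composite ids
    block_levels: list[str]           # env:trial:block composite ids

    @property
    def p(self) -> int:
        return len(self.env_levels)

    @property
    def v(self) -> int:
        return len(self.genotype_levels)

    @property
    def n(self) -> int:
        return int((~self.plots["missing"]).sum())

    @property
    def n_j(self) -> np.ndarray:
        obs = self.plots[~self.plots["missing"]]
        counts = obs.groupby("env_idx").size()
        out = np.zeros(self.p, dtype=int)
        out[counts.index.to_numpy()] = counts.to_numpy()
        return out

    def observed(self) -> pd.DataFrame:
        """Rows with a non-missing trait value."""
        return self.plots[~self.plots["missing"]]

    def subset_environments(self, keep: list[str]) -> "METDataset":
        """Dataset restricted to the named environments (level order preserved)."""
        keep_set = set(keep)
        unknown = keep_set - set(self.env_levels)
        if unknown:
            raise METDataError(f"unknown environments: {sorted(unknown)}")
        sub = self.plots[self.plots["env"].isin(keep_set)].copy()
        return load_met_dataset(
            sub[list(PHENOTYPE_COLUMNS)],
            env_order=[e for e in self.env_levels if e in keep_set],
            genotype_order=self.genotype_levels,
        )


def load_met_dataset(
    table: pd.DataFrame | str,
    env_order: list[str] | None = None,
    genotype_order: list[str] | None = None,
) -> METDataset:
    """Load and validate a plot-level phenotype table.

    Parameters
    ----------
    table
        DataFrame with columns ``env, trial, block, genotype, value`` or a
        path to a delimited text file with that header.
    env_order, genotype_order
        Optional explicit level orders.  Default is first-appearance order;
        loading/score vectors are order-sensitive so the chosen order is
        recorded on the returned dataset.
    """
    if isinstance(table, str):
        table = pd.read_csv(table)
    missing_cols = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing_cols:
        raise METDataError(f"phenotype table lacks columns: {sorted(missing_cols)}")
    df = table[list(PHENOTYPE_COLUMNS)].copy()
    for c in ("env", "trial", "block", "genotype"):
        df[c] = df[c].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="raise")

    key = df[["env", "trial", "block", "genotype"]].agg(":".join, axis=1)
    dup = key[key.duplicated()]
    if len(dup):
        raise METDataError(f"duplicated plot rows for keys: {sorted(set(dup))[:5]}")

    env_levels = _levels(df["env"], env_order)
    genotype_levels = _levels(df["genotype"], genotype_order)
    df["trial_id"] = df["env"] + ":" + df["trial"]
    df["block_id"] = df["trial_id"] + ":" + df["block"]
    trial_levels = list(dict.fromkeys(df["trial_id"]))
    block_levels = list(dict.fromkeys(df["block_id"]))

    env_idx = {e: i for i, e in enumerate(env_levels)}
    gen_idx = {g: i for i, g in enumerate(genotype_levels)}
    df["env_idx"] = df["env"].map(env_idx).astype(int)
    df["genotype_idx"] = df["genotype"].map(gen_idx).astype(int)
    df["trial_idx"] = df["trial_id"].map({t: i for i, t in enumerate(trial_levels)})
    df["block_idx"] = df["block_id"].map({b: i for i, b in enumerate(block_levels)})
    df["missing"] = df["value"].isna()

    ds = METDataset(df, env_levels, genotype_levels, trial_levels, block_levels)
    if (ds.n_j == 0).any():
        empty = [env_levels[j] for j in np.flatnonzero(ds.n_j == 0)]
        raise METDataError(f"environments without any non-missing plot: {empty}")
    return ds


# ---------------------------------------------------------------------------
# known environmental covariates


@dataclass
class CovariateMatrix:
    """Centred, unit-length known environment covariates.

    Each column of ``S`` has zero sum and unit Euclidean norm.  The centring
    offsets and scale divisors are retained so the identical transform can be
    applied to covariates of new (future) environments.
    """

    S: np.ndarray                 # p x q
    names: list[str]
    env_levels: list[str]
    offsets: np.ndarray           # q
    divisors: np.ndarray          # q

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @property
    def q(self) -> int:
        return self.S.shape[1]

    def transform(self, raw: pd.DataFrame) -> np.ndarray:
        """Apply the stored centring/scaling to raw covariates of new environments."""
        missing = set(self.names) - set(raw.columns)
        if missing:
            raise METDataError(f"new environments lack covariates: {sorted(missing)}")
        X = raw[self.names].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise METDataError("missing covariate values for new environments")
        return (X - self.offsets) / self.divisors


def prepare_covariates(
    raw: pd.DataFrame | str,
    env_levels: list[str] | None = None,
) -> CovariateMatrix:
    """Centre each covariate column and scale it to unit length.

    ``raw`` must be indexed by environment id (or contain an ``env`` column);
    rows are reordered to ``env_levels`` when given.  Constant columns are
    rejected because they have zero norm after centring.
    """
    if isinstance(raw, str):
        raw = pd.read_csv(raw)
    raw = raw.copy()
    if "env" in raw.columns:
        raw["env"] = raw["env"].astype(str)
        raw = raw.set_index("env")
    raw.index = raw.index.astype(str)
    if env_levels is not None:
        missing = set(env_levels) - set(raw.index)
        if missing:
            raise METDataError(f"covariate table lacks environments: {sorted(missing)}")
        raw = raw.loc[env_levels]
    env_levels = list(raw.index)
    X = raw.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [raw.columns[j] for j in np.flatnonzero(np.isnan(X).any(axis=0))]
        raise METDataError(f"missing covariate values in: {bad}")
    p, q = X.shape
    if q >= p:
        raise METDataError(f"need q < p environments; got q={q}, p={p}")
    offsets = X.mean(axis=0)
    centred = X - offsets
    divisors = np.linalg.norm(centred, axis=0)
    zero = divisors <= 1e-12 * max(1.0, np.abs(X).max())
    if zero.any():
        bad = [raw.columns[j] for j in np.flatnonzero(zero)]
        raise METDataError(f"constant covariate columns (zero norm after centring): {bad}")
    return CovariateMatrix(
        S=centred / divisors,
        names=[str(c) for c in raw.columns],
        env_levels=env_levels,
        offsets=offsets,
        divisors=divisors,
    )


# ---------------------------------------------------------------------------
# marker data


@dataclass
class MarkerMatrix:
    """Filtered, imputed and column-centred marker scores."""

    M: np.ndarray                 # v x m centred scores
    genotype_levels: list[str]
    marker_names: list[str]
    n_removed_monomorphic: int = 0
    n_removed_maf: int = 0
    n_removed_missing: int = 0

    @property
    def v(self) -> int:
        return self.M.shape[0]

    @property
    def m(self) -> int:
        return self.M.shape[1]


def read_marker_table(path_or_df: pd.DataFrame | str) -> pd.DataFrame:
    """Read a genotype x marker table; first column (or index) = genotype id."""
    if isinstance(path_or_df, str):
        df = pd.read_csv(path_or_df, index_col=0)
    else:
        df = path_or_df.copy()
        if "genotype" in df.columns:
            df = df.set_index("genotype")
    df.index = df.index.astype(str)
    return df.astype(float)


def impute_markers_knn(M_raw: np.ndarray, k: int = 10) -> np.ndarray:
    """Impute missing marker calls by the mean of the k nearest genotypes.

    Distance is Euclidean over mutually observed markers; neighbour means are
    unweighted; distance ties are broken by genotype index.  Imputed values
    are left continuous.  A genotype with no observed marker is rejected.
    """
    if k < 1:
        raise METDataError("k must be >= 1")
    M = np.asarray(M_raw, dtype=float).copy()
    obs = ~np.isnan(M)
    if (~obs).sum() == 0:
        return M
    if (obs.sum(axis=1) == 0).any():
        bad = np.flatnonzero(obs.sum(axis=1) == 0)
        raise METDataError(f"genotypes with all markers missing: {bad.tolist()}")
    v = M.shape[0]
    Z = np.where(obs, M, 0.0)
    # squared Euclidean distance restricted to mutually observed markers
    sq = Z**2
    shared = obs.astype(float) @ obs.T.astype(float)
    cross = Z @ Z.T
    s1 = sq @ obs.T.astype(float)
    d2 = s1 + s1.T - 2.0 * cross
    d2 = np.where(shared > 0, d2, np.inf)
    np.fill_diagonal(d2, np.inf)

    out = M.copy()
    need = np.flatnonzero(~obs.all(axis=1))
    for i in need:
        order = np.argsort(d2[i], kind="stable")  # index-order tie break
        for j in np.flatnonzero(~obs[i]):
            donors = order[obs[order, j]][:k]
            if len(donors) == 0:
                raise METDataError(f"marker column {j} unobserved among neighbours of genotype {i}")
            out[i, j] = M[donors, j].mean()
    return out


def filter_markers(
    raw: pd.DataFrame,
    maf_min: float = 0.00002,
    missing_max: float = 0.998,
    knn_k: int = 10,
) -> MarkerMatrix:
    """Filter, impute and centre a raw -1/0/1 marker table.

    Monomorphic columns are removed, then columns failing the minor allele
    frequency or missing-call thresholds; remaining missing calls are imputed
    by :func:`impute_markers_knn` and each surviving column is mean-centred.
    """
    if not (0 <= maf_min <= 1 and 0 <= missing_max <= 1):
        raise METDataError("thresholds must lie in [0, 1]")
    X = raw.to_numpy(dtype=float)
    names = [str(c) for c in raw.columns]
    obs = ~np.isnan(X)

    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(obs, X, np.nan), axis=0)
        mono = np.array([
            len(np.unique(X[obs[:, j], j])) <= 1 if obs[:, j].any() else True
            for j in range(X.shape[1])
        ])
    freq = (col_mean + 1.0) / 2.0            # major-allele frequency of the -1/0/1 codes
    maf = np.minimum(freq, 1.0 - freq)
    miss_rate = 1.0 - obs.mean(axis=0)

    keep = ~mono & (maf > maf_min) & (miss_rate < missing_max)
    if not keep.any():
        raise METDataError("all markers removed by filtering")
    Xk = impute_markers_knn(X[:, keep], k=knn_k)
    M = Xk - Xk.mean(axis=0)
    return MarkerMatrix(
        M=M,
        genotype_levels=list(raw.index.astype(str)),
        marker_names=[n for n, k_ in zip(names, keep) if k_],
        n_removed_monomorphic=int(mono.sum()),
        n_removed_maf=int((~mono & ~(maf > maf_min)).sum()),
        n_removed_missing=int((~mono & (maf > maf_min) & ~(miss_rate < missing_max)).sum()),
    )


# ---------------------------------------------------------------------------
# genomic relationship matrix


@dataclass
class GenomicRelationship:
    """VanRaden-style genomic relationship matrix ``G_g = M M' / m``."""

    G: np.ndarray
    genotype_levels: list[str]
    ridge: float = 0.0

    @property
    def v(self) -> int:
        return self.G.shape[0]

    def reorder(self, genotype_levels: list[str]) -> "GenomicRelationship":
        idx = {g: i for i, g in enumerate(self.genotype_levels)}
        missing = [g for g in genotype_levels if g not in idx]
        if missing:
            raise METDataError(f"genotypes without marker data: {missing}")
        sel = [idx[g] for g in genotype_levels]
        return GenomicRelationship(self.G[np.ix_(sel, sel)], list(genotype_levels), self.ridge)


def compute_grm(markers: MarkerMatrix, ridge: float = 0.0) -> GenomicRelationship:
    """``G_g = M M' / m`` from centred markers, optionally with a diagonal ridge.

    The un-ridged matrix from column-centred markers has zero row sums and is
    therefore singular; the REML engine adds its own solve-time ridge, so the
    default here is no ridge.
    """
    if markers.m < 1:
        raise METDataError("need at least one marker")
    G = markers.M @ markers.M.T / markers.m
    G = 0.5 * (G + G.T)
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return GenomicRelationship(G, list(markers.genotype_levels), float(ridge))


def write_grm(grm: GenomicRelationship, path: str) -> None:
    pd.DataFrame(grm.G, index=grm.genotype_levels, columns=grm.genotype_levels).to_csv(path)


def read_grm(path: str) -> GenomicRelationship:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return GenomicRelationship(df.to_numpy(dtype=float), list(df.index), 0.0)
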