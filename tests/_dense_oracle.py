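"""Independent dense evaluation of the restricted log-likelihood.

Builds the full n x n marginal covariance V explicitly at plot level and
evaluates the textbook REML expression

    l = -1/2 [ (n - p_x) log 2pi + log|V| + log|X' V^-1 X| + y' P y ].

Deliberately naive (explicit Kronecker products and dense solves) and kept
independent of the package's engine internals; usable only for tiny
instances.
"""

import numpy as np


def dense_reml_loglik(dataset, Gg_effective, Ge, sigma2_block, sigma2_resid):
    obs = dataset.observed()
    env = obs["env_idx"].to_numpy()
    gen = obs["genotype_idx"].to_numpy()
    blk = obs["block_idx"].to_numpy()
    y = obs["value"].to_numpy(dtype=float)
    n = len(y)
    p, v = dataset.p, dataset.v
    nb = len(dataset.block_levels)

    X = np.zeros((n, p))
    X[np.arange(n), env] = 1.0
    Z = np.zeros((n, p * v))
    Z[np.arange(n), env * v + gen] = 1.0
    Zb = np.zeros((n, nb))
    Zb[np.arange(n), blk] = 1.0

    blk_env = np.zeros(nb, dtype=int)
    blk_env[blk] = env
    G = np.kron(Ge, Gg_effective)
    V = Z @ G @ Z.T
    V += Zb @ np.diag(np.asarray(sigma2_block)[blk_env]) @ Zb.T
    V += np.diag(np.asarray(sigma2_resid)[env])

    sign, logdetV = np.linalg.slogdet(V)
    assert sign > 0
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    assert sign2 > 0
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    yPy = float(y @ P @ y)
    px = np.linalg.matrix_rank(X)
    return -0.5 * ((n - px) * np.log(2 * np.pi) + logdetV + logdetX + yPy)
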