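"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package internals: the mixed
model likelihood is evaluated on the dense stacked covariance matrix, and
general-dominance weights are recomputed as Shapley values by direct
enumeration of predictor orderings.
"""

from itertools import permutations

import numpy as np


def dense_loglik(dm, D, sigma, phi, method):
    """Stacked multivariate-normal log-likelihood with GLS beta.

    Builds the full N x N block-diagonal covariance
    ``V = blockdiag(Z_j D Z_j' + sigma^2 R_j(phi))`` and evaluates the
    Gaussian density directly (REML adds -1/2 log|X'V^{-1}X| and adjusts
    the 2*pi constant).
    """
    N, p = dm.n_obs, dm.X.shape[1]
    V = np.zeros((N, N))
    bounds = np.append(dm.site_starts, N)
    for j in range(dm.n_sites):
        sl = slice(bounds[j], bounds[j + 1])
        t = dm.t[sl]
        R = phi ** np.abs(t[:, None] - t[None, :]) if phi > 0 else np.eye(len(t))
        V[sl, sl] = dm.Z[sl] @ D @ dm.Z[sl].T + sigma**2 * R
    Vi = np.linalg.inv(V)
    XtViX = dm.X.T @ Vi @ dm.X
    beta = np.linalg.solve(XtViX, dm.X.T @ Vi @ dm.y)
    r = dm.y - dm.X @ beta
    _, logdet_v = np.linalg.slogdet(V)
    quad = float(r @ Vi @ r)
    if method == "ML":
        return -0.5 * (N * np.log(2 * np.pi) + logdet_v + quad)
    _, logdet_x = np.linalg.slogdet(XtViX)
    return -0.5 * ((N - p) * np.log(2 * np.pi) + logdet_v + logdet_x + quad)


def shapley_weights(r2_map, predictors):
    """Shapley values of the R2 game by enumerating all orderings."""
    predictors = list(predictors)
    total = {p: 0.0 for p in predictors}
    orderings = list(permutations(predictors))
    for order in orderings:
        seen = frozenset()
        for p in order:
            total[p] += r2_map[seen | {p}] - r2_map[seen]
            seen = seen | {p}
    return {p: total[p] / len(orderings) for p in predictors}
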