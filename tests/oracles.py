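"""Independent oracles for the twin-model likelihood.

Deliberately naive implementations, kept separate from the package's
vectorized code paths: per-pair densities via explicit 2×2 matrix algebra
/ scipy's multivariate normal, and a refining grid search over the
variance components and the mean.
"""

import numpy as np
from scipy.stats import multivariate_normal


def dense_pair_loglik(y1, y2, zygosity, a2, c2, e2, mu):
    """Sum of per-pair bivariate normal log densities, one explicit 2×2
    inversion per pair."""
    total = 0.0
    for x1, x2, z in zip(y1, y2, zygosity):
        v = a2 + c2 + e2
        rho = (1.0 if z == "MZ" else 0.5) * a2 + c2
        cov = np.array([[v, rho], [rho, v]])
        inv = np.linalg.inv(cov)
        sign, logdet = np.linalg.slogdet(cov)
        r = np.array([x1 - mu, x2 - mu])
        total += -np.log(2.0 * np.pi) - 0.5 * logdet - 0.5 * r @ inv @ r
    return total


def _group_loglik(points, a2, c2, e2, mu, genetic_weight):
    v = a2 + c2 + e2
    rho = genetic_weight * a2 + c2
    if v <= 0 or v * v - rho * rho <= 0:
        return -np.inf
    cov = np.array([[v, rho], [rho, v]])
    return multivariate_normal.logpdf(points, mean=[mu, mu], cov=cov).sum()


def grid_search_loglik(y1, y2, zygosity, n_grid=7, final_step=1e-3):
    """Maximized log-likelihood by a refining grid over (a², c², e², μ).

    Starts from moment-based centers and shrinks the grid span by 3× per
    level (so the step shrinks likewise) until every step is below
    ``final_step``.  Returns (best_loglik, best_params).
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    zygosity = np.asarray(zygosity, object)
    pts = {z: np.column_stack([y1[zygosity == z], y2[zygosity == z]])
           for z in ("MZ", "DZ")}
    allv = np.concatenate([y1, y2])
    V, mu0 = allv.var(), allv.mean()

    centers = np.array([V / 3.0, V / 3.0, V / 3.0, mu0])
    spans = np.array([V, V, V, 2.0 * allv.std() / np.sqrt(len(y1))])
    best_ll, best = -np.inf, centers.copy()
    while True:
        axes = []
        for c, s, is_var in zip(centers, spans, (True, True, True, False)):
            lo = max(0.0, c - s) if is_var else c - s
            axes.append(np.linspace(lo, c + s, n_grid))
        for a2 in axes[0]:
            for c2 in axes[1]:
                for e2 in axes[2]:
                    for mu in axes[3]:
                        ll = sum(
                            _group_loglik(pts[z], a2, c2, e2, mu, w)
                            for z, w in (("MZ", 1.0), ("DZ", 0.5))
                            if len(pts[z])
                        )
                        if ll > best_ll:
                            best_ll, best = ll, np.array([a2, c2, e2, mu])
        step = spans / (n_grid - 1) * 2.0
        if np.all(step <= final_step):
            return best_ll, best
        centers = best.copy()
        spans = spans / 3.0
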