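"""Minimal covariance-matrix-adaptation evolution strategy (CMA-ES).

Standard (mu/mu_w, lambda) CMA-ES with rank-one and rank-mu covariance
updates and cumulative step-size adaptation, for low-dimensional bounded
minimisation with a vectorised objective ``f(X) -> (lambda,)``.  Box
constraints are handled by projecting candidates onto the box before
evaluation.
"""

from __future__ import annotations

import numpy as np


def cma_es_minimise(objective, x0, sigma0: float, bounds, n_iter: int,
                    popsize: int, rng, ftol: float = 0.0):
    """Minimise ``objective`` over a box; returns (x_best, f_best, history).

    ``objective`` receives a (popsize, d) array of candidates (already
    clipped to bounds) and returns their objective values.
    """
    rng = np.random.default_rng(rng)
    x0 = np.asarray(x0, dtype=float)
    lo, hi = (np.broadcast_to(np.asarray(b, dtype=float), x0.shape)
              for b in bounds)
    d = len(x0)
    lam = max(popsize, 4)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / (w ** 2).sum()
    cc = (4 + mu_eff / d) / (d + 4 + 2 * mu_eff / d)
    cs = (mu_eff + 2) / (d + mu_eff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) /
              ((d + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (d + 1)) - 1) + cs
    chi_n = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d ** 2))

    mean = np.clip(x0, lo, hi)
    sigma = float(sigma0)
    C = np.eye(d)
    p_c = np.zeros(d)
    p_s = np.zeros(d)
    x_best, f_best = mean.copy(), np.inf
    history = []
    for _ in range(n_iter):
        try:
            A = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            C = np.eye(d)
            A = np.eye(d)
        z = rng.standard_normal((lam, d))
        y = z @ A.T
        x = np.clip(mean + sigma * y, lo, hi)
        f = np.asarray(objective(x), dtype=float)
        order = np.argsort(f)
        if f[order[0]] < f_best:
            f_best = float(f[order[0]])
            x_best = x[order[0]].copy()
        history.append(float(f[order[0]]))
        y_sel = (x[order[:mu]] - mean) / sigma  # respects the projection
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        C_inv_sqrt = np.linalg.inv(A)
        p_s = (1 - cs) * p_s + np.sqrt(cs * (2 - cs) * mu_eff) * \
            (C_inv_sqrt @ y_w)
        h_sig = (np.linalg.norm(p_s) /
                 np.sqrt(1 - (1 - cs) ** (2 * (len(history)))) <
                 (1.4 + 2 / (d + 1)) * chi_n)
        p_c = (1 - cc) * p_c + \
            h_sig * np.sqrt(cc * (2 - cc) * mu_eff) * y_w
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = ((1 - c1 - cmu) * C + c1 * (np.outer(p_c, p_c) +
             (not h_sig) * cc * (2 - cc) * C) + cmu * rank_mu)
        sigma *= float(np.exp((cs / damps) *
                              (np.linalg.norm(p_s) / chi_n - 1)))
        sigma = min(sigma, float(np.max(hi - lo)) or 1.0)
        if ftol and len(history) > 5 and \
                abs(history[-5] - history[-1]) < ftol:
            break
    return x_best, f_best, history
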