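"""Independent brute-force oracles for cross-checking the implementation.

These deliberately re-derive results from first principles (explicit
step-by-step moment formulas; dense numerical integration of the exact
posterior) and share no code with the package's computational paths.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm


def dl_oracle(y, v):
    """Spreadsheet-style evaluation of the DerSimonian-Laird equations.

    Returns (pooled, se, tau2, Q, H) computed step by step with explicit
    sums, independent of the package's implementation.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(y)
    w = 1.0 / v
    y_fixed = np.sum(w * y) / np.sum(w)
    Q = np.sum(w * (y - y_fixed) ** 2)
    df = k - 1
    if df > 0:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = (Q - df) / denom if denom > 0 else 0.0
        tau2 = tau2 if tau2 > 0 else 0.0
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    pooled = np.sum(w_star * y) / np.sum(w_star)
    se = np.sqrt(1.0 / np.sum(w_star))
    H = np.sqrt(Q / max(1, df))
    H = H if H > 1.0 else 1.0
    return pooled, se, tau2, Q, H


def grid_posterior_2trt(
    r1, n1, r2, n2,
    effect_prior_sd: float,
    tau_upper: float,
    n_d: int = 161,
    n_tau: int = 50,
    n_inner: int = 121,
    halfwidth_d: float = 2.0,
):
    """Exact posterior of the basic parameter d for a two-treatment network
    of two-arm dichotomous trials, by dense numerical integration.

    Model (identical to the sampler's): per study i, latent baseline mu_i and
    trial effect delta_i with r_i1 ~ Bin(n_i1, expit(mu_i)),
    r_i2 ~ Bin(n_i2, expit(mu_i + delta_i)), delta_i ~ N(d, tau^2),
    mu_i ~ N(0, effect_prior_sd^2), d ~ N(0, effect_prior_sd^2),
    tau ~ U(0, tau_upper).

    The per-study likelihood integral over (mu_i, delta_i) is evaluated on a
    fine 2-d grid; the (d, tau) posterior on an outer grid; tau is then
    integrated out.  Returns (d_grid, posterior_density, mean, median).
    """
    r1, n1 = np.asarray(r1, float), np.asarray(n1, float)
    r2, n2 = np.asarray(r2, float), np.asarray(n2, float)
    S = len(r1)

    # crude per-study centers for the integration windows
    l1 = np.log((r1 + 0.5) / (n1 - r1 + 0.5))
    l2 = np.log((r2 + 0.5) / (n2 - r2 + 0.5))
    se1 = np.sqrt(1.0 / (r1 + 0.5) + 1.0 / (n1 - r1 + 0.5))
    se2 = np.sqrt(1.0 / (r2 + 0.5) + 1.0 / (n2 - r2 + 0.5))
    d_center = np.mean(l2 - l1)
    d_grid = np.linspace(d_center - halfwidth_d, d_center + halfwidth_d, n_d)
    tau_grid = np.linspace(tau_upper / (2.0 * n_tau), tau_upper * (1 - 0.5 / n_tau), n_tau)

    log_post = np.zeros((n_d, n_tau))
    for i in range(S):
        hw = 6.0 * max(se1[i], 0.2) + 0.5
        mu_g = np.linspace(l1[i] - hw, l1[i] + hw, n_inner)
        hw2 = 6.0 * max(se2[i], 0.2) + 0.5 + tau_upper
        x_g = np.linspace(l2[i] - hw2, l2[i] + hw2, n_inner)  # x = mu + delta
        dmu = mu_g[1] - mu_g[0]
        dx = x_g[1] - x_g[0]
        ll1 = r1[i] * mu_g - n1[i] * np.logaddexp(0.0, mu_g) + norm.logpdf(
            mu_g, 0.0, effect_prior_sd)
        ll2 = r2[i] * x_g - n2[i] * np.logaddexp(0.0, x_g)
        # weight over the (x, mu) grid, flattened
        lw = (ll2[:, None] + ll1[None, :]).ravel()
        dl = (x_g[:, None] - mu_g[None, :]).ravel()  # delta = x - mu
        keep = lw > lw.max() - 40.0
        lw, dl = lw[keep], dl[keep]
        for j, tau in enumerate(tau_grid):
            # integral over (mu, delta) for every d at this tau
            ld = norm.logpdf(dl[None, :], d_grid[:, None], tau)
            log_post[:, j] += logsumexp(lw[None, :] + ld, axis=1) + np.log(dmu * dx)

    log_post += norm.logpdf(d_grid, 0.0, effect_prior_sd)[:, None]
    # integrate tau out (uniform prior; equal spacing)
    log_d = logsumexp(log_post, axis=1)
    log_d -= logsumexp(log_d)
    dens = np.exp(log_d)
    dd = d_grid[1] - d_grid[0]
    mean = float(np.sum(d_grid * dens))
    cdf = np.cumsum(dens)
    j = int(np.searchsorted(cdf, 0.5))
    # linear interpolation for the median
    c0 = cdf[j - 1] if j > 0 else 0.0
    median = float(d_grid[j] - dd / 2.0 + dd * (0.5 - c0) / max(cdf[j] - c0, 1e-300))
    return d_grid, dens / dd, mean, median
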