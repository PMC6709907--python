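"""Independent oracles for the test suite.

These compute reference answers by routes that share no code with the
package's samplers: dense-grid numeric posterior integration for small
models, the classical t-tail for the flat-prior two-group contrast, and the
textbook split-R-hat formula.  They are deliberately slow and simple.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit


def _cdf_at_zero(grid: np.ndarray, density: np.ndarray) -> float:
    """P(x < 0) for a density known on a fine grid (trapezoid + interpolation)."""
    density = density / np.trapezoid(density, grid)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (density[1:] + density[:-1]))])
    cum /= cum[-1]
    return float(np.interp(0.0, grid, cum))


def grid_p_minus_lognormal(y, x, priors, n_grid: int = 161) -> float:
    """P(beta < 0) for the two-group lognormal model by grid integration.

    Model: log y_i ~ Normal(alpha + beta * x_i, sigma), priors
    alpha ~ N(loc_a, s_a), beta ~ N(0, s_b), sigma ~ HalfNormal(s_s),
    integrated on a dense (alpha, beta, log sigma) grid.
    """
    z = np.log(np.asarray(y, dtype=float))
    x = np.asarray(x, dtype=float)
    z0, z1 = z[x == 0], z[x == 1]
    n0, n1 = len(z0), len(z1)
    ahat = z0.mean()
    bhat = z1.mean() - ahat
    resid = np.concatenate([z0 - z0.mean(), z1 - z1.mean()])
    sd = max(np.sqrt(np.sum(resid**2) / max(len(z) - 2, 1)), 1e-3)
    se_a, se_b = sd / np.sqrt(n0), sd * np.sqrt(1 / n0 + 1 / n1)

    alpha = np.linspace(ahat - 10 * se_a, ahat + 10 * se_a, n_grid)
    beta = np.linspace(bhat - 10 * se_b, bhat + 10 * se_b, n_grid)
    logsig = np.linspace(np.log(sd) - 2.5, np.log(sd) + 2.5, n_grid)

    A = alpha[:, None, None]
    B = beta[None, :, None]
    S = np.exp(logsig)[None, None, :]
    # sufficient statistics per group
    s0, q0 = z0.sum(), np.sum(z0**2)
    s1, q1 = z1.sum(), np.sum(z1**2)
    sse = (q0 - 2 * A * s0 + n0 * A**2) + (q1 - 2 * (A + B) * s1 + n1 * (A + B) ** 2)
    loglik = -0.5 * sse / S**2 - (n0 + n1) * np.log(S)
    logprior = (
        -0.5 * ((A - priors["alpha"].location) / priors["alpha"].scale) ** 2
        - 0.5 * (B / priors["beta"].scale) ** 2
        - 0.5 * (S / priors["sigma"].scale) ** 2
        + np.log(S)  # Jacobian of the log-sigma grid
    )
    logpost = loglik + logprior
    logpost -= logpost.max()
    marg_beta = np.exp(logpost).sum(axis=(0, 2))
    return _cdf_at_zero(beta, marg_beta)


def grid_p_minus_binomial(k, n, x, priors, n_grid: int = 401) -> float:
    """P(beta < 0) for the two-group binomial-logit model by grid integration."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    x = np.asarray(x, dtype=float)
    k0, n0 = k[x == 0].sum(), n[x == 0].sum()
    k1, n1 = k[x == 1].sum(), n[x == 1].sum()
    p0 = np.clip(k0 / n0, 1e-3, 1 - 1e-3)
    p1 = np.clip(k1 / n1, 1e-3, 1 - 1e-3)
    ahat = np.log(p0 / (1 - p0))
    bhat = np.log(p1 / (1 - p1)) - ahat
    se_a = 1 / np.sqrt(n0 * p0 * (1 - p0))
    se_b = np.sqrt(se_a**2 + 1 / (n1 * p1 * (1 - p1)))

    alpha = np.linspace(ahat - 10 * se_a, ahat + 10 * se_a, n_grid)
    beta = np.linspace(bhat - 10 * se_b, bhat + 10 * se_b, n_grid)
    A = alpha[:, None]
    B = beta[None, :]
    loglik = k0 * A - n0 * np.logaddexp(0, A) + k1 * (A + B) - n1 * np.logaddexp(0, A + B)
    logprior = (
        -0.5 * ((A - priors["alpha"].location) / priors["alpha"].scale) ** 2
        - 0.5 * (B / priors["beta"].scale) ** 2
    )
    logpost = loglik + logprior
    logpost -= logpost.max()
    marg_beta = np.exp(logpost).sum(axis=0)
    return _cdf_at_zero(beta, marg_beta)


def t_tail_p_minus(y, x) -> float:
    """Classical one-sided tail probability of the two-group log-scale contrast.

    Under flat priors on (alpha, beta, log sigma) the posterior of beta is a
    scaled-shifted Student t with n-2 degrees of freedom, so P(beta < 0)
    equals the frequentist one-sided p-value of the Welch-free pooled t test.
    """
    z = np.log(np.asarray(y, dtype=float))
    x = np.asarray(x, dtype=float)
    z0, z1 = z[x == 0], z[x == 1]
    n0, n1 = len(z0), len(z1)
    bhat = z1.mean() - z0.mean()
    sp2 = (np.sum((z0 - z0.mean()) ** 2) + np.sum((z1 - z1.mean()) ** 2)) / (n0 + n1 - 2)
    se = np.sqrt(sp2 * (1 / n0 + 1 / n1))
    return float(stats.t.cdf(-bhat / se, df=n0 + n1 - 2))


def split_rhat_formula(chains: np.ndarray) -> float:
    """Textbook split Gelman-Rubin statistic, written independently."""
    x = np.asarray(chains, dtype=float)
    half = x.shape[1] // 2
    parts = [c[:half] for c in x] + [c[x.shape[1] - half :] for c in x]
    parts = np.asarray(parts)
    m, n = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def exact_binomial_pp_difference(alpha: float, beta: float) -> float:
    """Percentage-point difference implied by logit-scale coefficients."""
    return 100.0 * (expit(alpha + beta) - expit(alpha))
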