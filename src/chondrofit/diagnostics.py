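"""MCMC convergence diagnostics: split Gelman-Rubin R-hat and effective
sample size.

The acceptance bound used throughout the package is R-hat < 1.02 for every
parameter; ESS is expected in the hundreds or thousands.  Degenerate
(constant) chains have no defined diagnostic and yield the ``nan`` sentinel,
which downstream code treats as a convergence flag, never an exception.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["compute_rhat", "compute_ess", "RHAT_BOUND"]

#: Convergence acceptance bound on split R-hat.
RHAT_BOUND = 1.02


def compute_rhat(chains: np.ndarray) -> float:
    """Split Gelman-Rubin statistic for one parameter.

    Parameters
    ----------
    chains : array (n_chains, n_iterations)
        Needs >= 2 chains of >= 4 iterations.  Each chain is split in half,
        and R-hat is computed from the between- and within-half variances;
        well-mixed chains give values near 1.

    Returns
    -------
    float
        The statistic, or ``nan`` when all chains have zero within-chain
        variance (constant chains).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need a (chains >= 2, iterations >= 4) array")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, x.shape[1] - n :]], axis=0)  # (2m, n)
    m = halves.shape[0]
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    if w == 0.0:
        return float("nan")
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    # the estimator can dip below 1 by sampling noise; that carries no
    # information about non-convergence, so floor at the ideal value
    return float(max(np.sqrt(var_plus / w), 1.0))


def compute_ess(chains: np.ndarray) -> float:
    """Autocorrelation-based (bulk) effective sample size for one parameter.

    Wraps the standard arviz estimator; constant chains return the ``nan``
    sentinel since autocorrelation is undefined there.
    """
    import arviz as az

    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need a (chains >= 2, iterations >= 4) array")
    if np.all(x == x.flat[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x, method="bulk"))


def diagnose(draws: np.ndarray, names: list[str]) -> tuple[dict, dict]:
    """Per-parameter R-hat and ESS for draws shaped (chains, iters, params).

    ESS is computed in one batched arviz call (per-parameter calls carry
    substantial conversion overhead); constant parameters get the sentinel.
    """
    import arviz as az

    rhat = {name: compute_rhat(draws[:, :, j]) for j, name in enumerate(names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset = az.convert_to_dataset(np.ascontiguousarray(draws))
        ess_arr = np.asarray(az.ess(dataset, method="bulk").to_array()).ravel()
    ess = {}
    for j, name in enumerate(names):
        col = draws[:, :, j]
        ess[name] = float("nan") if np.all(col == col.flat[0]) else float(ess_arr[j])
    return rhat, ess
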