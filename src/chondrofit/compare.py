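"""Posterior predictive checks and approximate leave-one-out cross-validation.

The model-checking toolkit: PPC test statistics (mean, sd, min, max and
per-genotype means) with tail probabilities, and PSIS-LOO — importance
ratios smoothed by a generalized-Pareto fit to their upper tail — to compare
models by expected log pointwise predictive density (elpd).  Used in
particular to ask whether a genotype x treatment interaction improves
generalization in the paired limb-explant design.  For small datasets an
exact refit-LOO fallback is available and is used automatically when any
Pareto k exceeds 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .data import MeasurementTable, SchemaError, StudyDesign
from .model import BayesGLM
from .sampler import SamplerConfig

__all__ = [
    "PpcResult",
    "LooResult",
    "ModelComparison",
    "posterior_predictive_replicates",
    "ppc_pvalue",
    "ppc_summary",
    "psis_loo",
    "exact_loo",
    "compare_interaction_models",
]

PARETO_K_WARN = 0.7


# --------------------------------------------------------------------- #
# posterior predictive checks
def posterior_predictive_replicates(results, n_rep: int, seed: int = 0) -> np.ndarray:
    """Simulate ``n_rep`` response vectors from the fitted likelihood.

    Each replicate uses the design rows of the observed table and the
    parameter values of one posterior draw.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    model = results.model
    rng = np.random.default_rng(seed)
    flat = results.draws.reshape(results.n_draws, len(results.param_names))
    idx = rng.choice(results.n_draws, size=n_rep, replace=n_rep > results.n_draws)
    names = results.param_names
    reps = np.empty((n_rep, model.table.n))
    for r, i in enumerate(idx):
        params = dict(zip(names, flat[i]))
        eta = model.eta_from_params(params)
        if model.family == "lognormal":
            reps[r] = np.exp(rng.normal(eta, float(params["sigma"])))
        else:
            reps[r] = rng.binomial(model.ntot.astype(int), expit(eta))
    return reps


def ppc_pvalue(observed_stat: float, replicated_stats) -> float:
    """Fraction of replicated statistics >= the observed one."""
    reps = np.asarray(list(replicated_stats), dtype=float)
    if reps.size == 0:
        raise ValueError("no replicated statistics")
    return float(np.mean(reps >= observed_stat))


@dataclass
class PpcResult:
    statistic_name: str
    observed: float
    ppc_p: float
    replicated: np.ndarray = field(repr=False)

    @property
    def consistent(self) -> bool:
        return 0.05 <= self.ppc_p <= 0.95

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "ppc_p": round(self.ppc_p, 3),
            "consistent": self.consistent,
        }


def _response_scale(model: BayesGLM, y: np.ndarray) -> np.ndarray:
    # counts are checked on the labelling-rate scale, lengths on their own scale
    if model.family == "binomial_logit":
        return y / model.ntot
    return y


def ppc_summary(results, n_rep: int = 500, seed: int = 0) -> list[PpcResult]:
    """PPC over the fixed statistics: mean, sd, min, max, per-genotype mean."""
    model = results.model
    reps = posterior_predictive_replicates(results, n_rep, seed)
    obs = _response_scale(model, model.table.response().astype(float))
    reps = _response_scale(model, reps)

    stats: dict[str, callable] = {
        "mean": lambda v: float(np.mean(v)),
        "sd": lambda v: float(np.std(v, ddof=1)),
        "min": lambda v: float(np.min(v)),
        "max": lambda v: float(np.max(v)),
    }
    out = []
    for name, fn in stats.items():
        rep_stats = np.array([fn(r) for r in reps])
        out.append(PpcResult(name, fn(obs), ppc_pvalue(fn(obs), rep_stats), rep_stats))
    if "genotype" in model.table.factor_levels:
        codes = model.table.codes("genotype")
        for j, lvl in enumerate(model.table.factor_levels["genotype"]):
            mask = codes == j
            o = float(np.mean(obs[mask]))
            rep_stats = reps[:, mask].mean(axis=1)
            out.append(PpcResult(f"group_mean[{lvl}]", o, ppc_pvalue(o, rep_stats), rep_stats))
    return out


# --------------------------------------------------------------------- #
# PSIS-LOO
@dataclass
class LooResult:
    elpd: float
    se: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray
    method: str = "psis"

    @property
    def flagged_points(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.pareto_k > PARETO_K_WARN)]

    def to_dict(self) -> dict:
        return {
            "elpd": self.elpd,
            "se": self.se,
            "method": self.method,
            "pointwise_elpd": self.pointwise_elpd.tolist(),
            "pareto_k": self.pareto_k.tolist(),
            "flagged_points": self.flagged_points,
        }


def psis_loo(loglik: np.ndarray) -> LooResult:
    """Pareto-smoothed importance-sampling LOO from a (draws, obs) matrix.

    Per observation, the importance ratios 1/p(y_i | theta_s) are smoothed by
    a generalized-Pareto fit to their upper tail (arviz's ``psislw``), then
    elpd_i = log sum_s w_s p(y_i | theta_s).  The standard error follows from
    the spread of the pointwise values.  A column that is -inf for every draw
    carries no predictive information: it is flagged (k = inf) and excluded
    from the elpd sum with a warning.
    """
    import arviz as az

    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("log-likelihood matrix must be (draws, observations)")
    s, n = ll.shape
    pointwise = np.empty(n)
    ks = np.empty(n)
    dropped = []
    for i in range(n):
        col = ll[:, i]
        if not np.any(np.isfinite(col)):
            pointwise[i] = np.nan
            ks[i] = np.inf
            dropped.append(i)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lw, k = az.psislw(-col)
        pointwise[i] = float(logsumexp(lw + col))
        ks[i] = float(k)
    if dropped:
        warnings.warn(f"observations {dropped} had -inf log-likelihood for all draws; excluded from elpd")
    finite = np.isfinite(pointwise)
    elpd = float(np.sum(pointwise[finite]))
    nf = int(finite.sum())
    se = float(np.sqrt(nf * np.var(pointwise[finite], ddof=1))) if nf > 1 else 0.0
    return LooResult(elpd, se, pointwise, ks, method="psis")


def exact_loo(model: BayesGLM, config: SamplerConfig) -> LooResult:
    """Exact leave-one-out: refit dropping each observation and score it.

    Intended for small n (<= a few dozen); used as the automatic fallback
    when PSIS tail diagnostics fail.
    """
    table = model.table
    n = table.n
    pointwise = np.empty(n)
    for i in range(n):
        df_i = table.df.drop(index=i).reset_index(drop=True)
        table_i = MeasurementTable(df_i, kind=table.kind, metadata=table.metadata)
        model_i = BayesGLM(table_i, model.design, priors=model.priors, pooled_group_intercepts=model.pooled)
        res_i = model_i.fit(config)
        flat = res_i.draws.reshape(res_i.n_draws, len(res_i.param_names))
        # score the held-out row under each draw of the reduced fit
        ll = _loglik_for_row(model, res_i.param_names, flat, i)
        pointwise[i] = float(logsumexp(ll) - np.log(ll.size))
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * np.var(pointwise, ddof=1)))
    return LooResult(elpd, se, pointwise, np.zeros(n), method="exact")


def _loglik_for_row(model: BayesGLM, names: list[str], flat: np.ndarray, i: int) -> np.ndarray:
    """Pointwise log-likelihood of row i of ``model`` under external draws.

    Group-intercept levels present only in the held-out row (unseen in the
    reduced fit) get intercept 0 — the prior mean — which is the correct
    predictive treatment for a new group level under sum-to-zero coding.
    """
    out = np.empty(flat.shape[0])
    name_idx = {n: j for j, n in enumerate(names)}
    for s in range(flat.shape[0]):
        params = {}
        for pname in model.param_names:
            params[pname] = flat[s, name_idx[pname]] if pname in name_idx else 0.0
        out[s] = model.pointwise_log_likelihood(params, i)
    return out


# --------------------------------------------------------------------- #
# interaction vs no-interaction comparison
@dataclass
class ModelComparison:
    """PSIS-LOO comparison of the interaction and no-interaction models."""

    elpd_interaction: float
    elpd_no_interaction: float
    elpd_diff: float  # interaction - no_interaction
    diff_se: float
    preferred: str  # "interaction" | "no_interaction" | "indistinguishable"
    loo_interaction: LooResult = field(repr=False)
    loo_no_interaction: LooResult = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "elpd_interaction": self.elpd_interaction,
            "elpd_no_interaction": self.elpd_no_interaction,
            "elpd_diff": self.elpd_diff,
            "diff_se": self.diff_se,
            "preferred": self.preferred,
            "rule": "prefer higher elpd when |elpd_diff| > 2 * diff_se, else indistinguishable",
            "pareto_k_max": float(
                max(np.max(self.loo_interaction.pareto_k), np.max(self.loo_no_interaction.pareto_k))
            ),
        }


def _loo_with_fallback(model: BayesGLM, results, config: SamplerConfig) -> LooResult:
    loo = psis_loo(results.loglik_matrix())
    if loo.flagged_points and model.table.n <= 30:
        loo = exact_loo(model, config)
    return loo


def compare_interaction_models(
    table: MeasurementTable,
    design: StudyDesign,
    config: SamplerConfig | None = None,
    require_convergence: bool = True,
) -> ModelComparison:
    """Fit the design with and without its interaction and compare by LOO.

    The decision rule: the higher-elpd model is preferred when the elpd
    difference exceeds twice its standard error (computed from the pointwise
    elpd differences); otherwise the models are indistinguishable.
    """
    if len(design.effect_terms) < 2:
        raise SchemaError("interaction comparison needs two effect terms (e.g. genotype and treatment)")
    config = config or SamplerConfig()
    results = {}
    models = {}
    for label, inter in (("interaction", True), ("no_interaction", False)):
        d = StudyDesign(
            family=design.family,
            effect_terms=list(design.effect_terms),
            interaction=inter,
            group_intercept_factors=list(design.group_intercept_factors),
        )
        m = BayesGLM(table, d)
        res = m.fit(config)
        if require_convergence and not res.converged:
            raise RuntimeError(
                f"{label} model failed the convergence gate "
                f"(max R-hat {res.max_rhat:.4f} >= 1.02); comparison aborted"
            )
        models[label], results[label] = m, res

    loo_i = _loo_with_fallback(models["interaction"], results["interaction"], config)
    loo_n = _loo_with_fallback(models["no_interaction"], results["no_interaction"], config)
    d_i = np.where(np.isfinite(loo_i.pointwise_elpd), loo_i.pointwise_elpd, 0.0)
    d_n = np.where(np.isfinite(loo_n.pointwise_elpd), loo_n.pointwise_elpd, 0.0)
    diff = d_i - d_n
    elpd_diff = float(diff.sum())
    diff_se = float(np.sqrt(diff.size * np.var(diff, ddof=1))) if diff.size > 1 else 0.0
    if abs(elpd_diff) <= 2.0 * diff_se:
        preferred = "indistinguishable"
    else:
        preferred = "interaction" if elpd_diff > 0 else "no_interaction"
    return ModelComparison(
        elpd_interaction=loo_i.elpd,
        elpd_no_interaction=loo_n.elpd,
        elpd_diff=elpd_diff,
        diff_se=diff_se,
        preferred=preferred,
        loo_interaction=loo_i,
        loo_no_interaction=loo_n,
    )
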