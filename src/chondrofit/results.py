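"""Fit results: posterior draws, diagnostics, effect-direction probabilities.

The significance currency is the pair of effect-direction probabilities
(p-, p+): the posterior probability that an effect coefficient is negative
or positive.  They always sum to one; p- >= 0.950 (equivalently p+ <= 0.050)
or vice versa is regarded as significant, thresholding inclusively.
Probabilities are reported to 3 digits, with extreme values reported as
bounds ("< 0.001" / "> 0.999") when no draw crosses zero at the realized
Monte Carlo resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .diagnostics import RHAT_BOUND, diagnose

__all__ = [
    "EffectDirectionResult",
    "BayesGLMResults",
    "effect_direction",
    "classify_significance",
    "format_probability",
]

LABELS = ("negative_significant", "positive_significant", "not_significant")
SIGNIFICANCE_THRESHOLD = 0.950


def effect_direction(draws: np.ndarray) -> tuple[float, float]:
    """(p-, p+) from pooled posterior draws of one coefficient.

    p- is the fraction of draws strictly below zero; draws exactly at zero
    (measure zero for continuous posteriors) count towards p+; p+ = 1 - p-.
    """
    d = np.asarray(draws, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("no draws")
    p_minus = float(np.count_nonzero(d < 0.0)) / d.size
    return p_minus, 1.0 - p_minus


def classify_significance(p_minus: float, p_plus: float) -> str:
    """Label the direction call; threshold 0.950, inclusive."""
    if abs((p_minus + p_plus) - 1.0) > 1e-12:
        raise ValueError("p_minus + p_plus must equal 1")
    if p_minus >= SIGNIFICANCE_THRESHOLD:
        return "negative_significant"
    if p_plus >= SIGNIFICANCE_THRESHOLD:
        return "positive_significant"
    return "not_significant"


def format_probability(p: float, n_draws: int) -> str:
    """Three-digit rendering with bound notation below Monte Carlo resolution.

    A probability smaller than 1/n_draws cannot be distinguished from zero by
    the sampler, so it is reported as a bound ("< 0.001" for a few thousand
    draws); symmetrically for probabilities above 1 - 1/n_draws.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    resolution = 1.0 / n_draws
    text = f"{p:.3f}"
    if p < resolution or text == "0.000":
        bound = max(math.ceil(resolution * 1000) / 1000, 0.001)
        return f"< {bound:.3f}"
    if p > 1.0 - resolution or text == "1.000":
        bound = min(math.floor((1.0 - resolution) * 1000) / 1000, 0.999)
        return f"> {bound:.3f}"
    return text


@dataclass
class EffectDirectionResult:
    """Effect-direction probabilities and effect size for one coefficient."""

    parameter: str
    p_minus: float
    p_plus: float
    label: str
    effect_median: float
    effect_ci_low: float
    effect_ci_high: float
    effect_unit: str  # "percent change" (lognormal) | "percentage points" (binomial)
    n_draws: int

    @property
    def p_minus_text(self) -> str:
        return format_probability(self.p_minus, self.n_draws)

    @property
    def p_plus_text(self) -> str:
        return format_probability(self.p_plus, self.n_draws)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "p_minus": round(self.p_minus, 3),
            "p_plus": round(self.p_plus, 3),
            "p_minus_text": self.p_minus_text,
            "p_plus_text": self.p_plus_text,
            "label": self.label,
            "effect_summary": {
                "median": self.effect_median,
                "ci_low": self.effect_ci_low,
                "ci_high": self.effect_ci_high,
                "unit": self.effect_unit,
                "ci_level": 0.90,
            },
        }


class BayesGLMResults:
    """Posterior draws plus diagnostics for a fitted :class:`BayesGLM`.

    Draws are stored per chain in the reported parameterization (group
    intercepts expanded to all levels, sigma on its natural scale).  R-hat
    and ESS are computed for every parameter at construction; ``converged``
    is True only when every R-hat is finite and below 1.02.
    """

    def __init__(self, model, draws: np.ndarray, param_names: list[str], config, sampler_stats: dict):
        self.model = model
        self.draws = np.asarray(draws, dtype=float)  # (chains, iters, params)
        self.param_names = list(param_names)
        self.config = config
        self.sampler_stats = sampler_stats
        self.rhat, self.ess = diagnose(self.draws, self.param_names)

    # ------------------------------------------------------------------ #
    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        if len(vals) < len(self.rhat):
            return float("nan")  # a sentinel anywhere means the run is flagged
        return max(vals)

    @property
    def min_ess(self) -> float:
        vals = [v for v in self.ess.values() if np.isfinite(v)]
        if len(vals) < len(self.ess):
            return float("nan")
        return min(vals)

    @property
    def converged(self) -> bool:
        mr = self.max_rhat
        return bool(np.isfinite(mr) and mr < RHAT_BOUND)

    # ------------------------------------------------------------------ #
    def get(self, parameter: str) -> np.ndarray:
        """Pooled draws of one parameter."""
        if parameter not in self.param_names:
            raise KeyError(f"unknown parameter {parameter!r}")
        j = self.param_names.index(parameter)
        return self.draws[:, :, j].ravel()

    def effect_direction(self, parameter: str | None = None) -> tuple[float, float]:
        parameter = parameter or self.model.effect_of_interest
        return effect_direction(self.get(parameter))

    def _group_intercept_mean(self) -> np.ndarray:
        """Per-draw mean group intercept, summed over group factors."""
        ubar = np.zeros(self.n_draws)
        for g in self.model.groups:
            cols = [self.param_names.index(f"u_{g.factor}[{lvl}]") for lvl in g.levels]
            ubar += self.draws[:, :, cols].reshape(self.n_draws, len(cols)).mean(axis=1)
        return ubar

    def effect_size_summary(self, parameter: str | None = None, ci: float = 0.90) -> dict:
        """Effect size on the measurement scale, median and central CI.

        lognormal: percent change ``100 * (exp(beta) - 1)``.
        binomial: percentage-point difference
        ``100 * (logistic(alpha + beta + u_bar) - logistic(alpha + u_bar))``
        with u_bar the per-draw mean group intercept.
        """
        parameter = parameter or self.model.effect_of_interest
        beta = self.get(parameter)
        if self.model.family == "lognormal":
            per_draw = 100.0 * (np.exp(beta) - 1.0)
            unit = "percent change"
        else:
            alpha = self.get("alpha")
            ubar = self._group_intercept_mean()
            per_draw = 100.0 * (expit(alpha + beta + ubar) - expit(alpha + ubar))
            unit = "percentage points"
        lo, hi = np.quantile(per_draw, [(1 - ci) / 2, (1 + ci) / 2])
        return {"median": float(np.median(per_draw)), "ci_low": float(lo), "ci_high": float(hi), "unit": unit}

    def effect_result(self, parameter: str | None = None) -> EffectDirectionResult:
        parameter = parameter or self.model.effect_of_interest
        p_minus, p_plus = self.effect_direction(parameter)
        size = self.effect_size_summary(parameter)
        return EffectDirectionResult(
            parameter=parameter,
            p_minus=p_minus,
            p_plus=p_plus,
            label=classify_significance(p_minus, p_plus),
            effect_median=size["median"],
            effect_ci_low=size["ci_low"],
            effect_ci_high=size["ci_high"],
            effect_unit=size["unit"],
            n_draws=self.n_draws,
        )

    def effect_results(self) -> list[EffectDirectionResult]:
        """One result per effect and interaction coefficient."""
        return [self.effect_result(name) for name in self.model.beta_names]

    # ------------------------------------------------------------------ #
    def credible_interval(self, parameter: str, level: float = 0.90) -> tuple[float, float]:
        d = self.get(parameter)
        lo, hi = np.quantile(d, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def loglik_matrix(self) -> np.ndarray:
        """Pointwise log-likelihood, (total draws, n_obs)."""
        flat = self.draws.reshape(self.n_draws, len(self.param_names))
        return self.model.loglik_matrix(flat)

    # ------------------------------------------------------------------ #
    def summary(self) -> pd.DataFrame:
        """Posterior summary table: moments, 90% interval, R-hat, ESS."""
        flat = self.draws.reshape(self.n_draws, len(self.param_names))
        q05, q50, q95 = np.quantile(flat, [0.05, 0.5, 0.95], axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "5%": q05,
                "median": q50,
                "95%": q95,
                "rhat": [self.rhat[n] for n in self.param_names],
                "ess": [self.ess[n] for n in self.param_names],
            },
            index=self.param_names,
        )

    def draws_frame(self) -> pd.DataFrame:
        """Columnar draws with chain and iteration index columns."""
        chains, iters, _ = self.draws.shape
        df = pd.DataFrame(
            self.draws.reshape(chains * iters, len(self.param_names)), columns=self.param_names
        )
        df.insert(0, "iteration", np.tile(np.arange(iters), chains))
        df.insert(0, "chain", np.repeat(np.arange(chains), iters))
        return df

    def save_draws(self, path) -> None:
        self.draws_frame().to_csv(path, index=False)

    def __repr__(self) -> str:
        conv = "converged" if self.converged else "NOT CONVERGED (flagged)"
        return (
            f"<BayesGLMResults {self.model.family}, {self.draws.shape[0]} chains x "
            f"{self.draws.shape[1]} draws, max R-hat {self.max_rhat:.4f} [{conv}]>"
        )
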