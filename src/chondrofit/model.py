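"""Bayesian GLMs for skeletal phenotyping measurements.

Two noise families cover the measurement types:

* ``lognormal`` — positive continuous responses y (lengths, qPCR relative
  quantities): ``log y_i ~ Normal(eta_i, sigma)``.
* ``binomial_logit`` — labelled/total cell counts:
  ``labelled_i ~ Binomial(total_i, logistic(eta_i))``.

The linear predictor is ``eta_i = alpha + sum_k beta_k x_ik + sum_f u_f[g_f(i)]``
with an optional pairwise interaction term.  Effects coming from batches,
litters or animals enter as separate per-level intercepts u with a broad
shared prior, constrained to sum to zero within each factor so they are
identifiable against the global intercept alpha.  Priors are deliberately
much broader than the spread of the data on the link scale, so posteriors
are determined by the data.

:class:`BayesGLM` is the model object; :meth:`BayesGLM.fit` runs MCMC and
returns a :class:`~chondrofit.results.BayesGLMResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, xlogy

from .data import MeasurementTable, SchemaError, StudyDesign, validate_against_design

__all__ = ["PriorSpec", "ModelSpec", "BayesGLM", "default_priors"]

_LOG2PI = float(np.log(2.0 * np.pi))

try:  # JIT kernels for the sampling hot path; numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=True, error_model="numpy")
    def _ln_kernel(theta, X, z, codes, K, pa_loc, pa_sc, pb_loc, pb_sc, gu_sc, ps_sc, logy_sum):
        d = theta.shape[0]
        n = z.shape[0]
        nb = X.shape[1]
        grad = np.zeros(d)
        for i in range(d):
            t = theta[i]
            if not np.isfinite(t) or abs(t) > 1e8:
                return -np.inf, grad
        alpha = theta[0]
        iv = 1 + nb
        Km1 = K - 1 if K > 0 else 0
        ils = iv + Km1
        log_sigma = theta[ils]
        if log_sigma > 300.0:
            log_sigma = 300.0
        if log_sigma < -150.0:
            log_sigma = -150.0
        sigma2 = np.exp(2.0 * log_sigma)
        u = np.zeros(K + 1)
        if K > 0:
            ssum = 0.0
            for j in range(Km1):
                u[j] = theta[iv + j]
                ssum += u[j]
            u[K - 1] = -ssum
        du = np.zeros(K + 1)
        rss = 0.0
        ga = 0.0
        for i in range(n):
            eta = alpha
            for j in range(nb):
                eta += X[i, j] * theta[1 + j]
            if K > 0:
                eta += u[codes[i]]
            r = z[i] - eta
            rss += r * r
            de = r / sigma2
            ga += de
            for j in range(nb):
                grad[1 + j] += X[i, j] * de
            if K > 0:
                du[codes[i]] += de
        lp = -0.5 * rss / sigma2 - n * (log_sigma + 0.5 * 1.8378770664093453) - logy_sum
        grad[0] = ga
        grad[ils] = rss / sigma2 - n
        for j in range(Km1):
            grad[iv + j] += du[j] - du[K - 1]
        lp += -0.5 * ((alpha - pa_loc) / pa_sc) ** 2
        grad[0] += -(alpha - pa_loc) / pa_sc**2
        for j in range(nb):
            b = theta[1 + j] - pb_loc
            lp += -0.5 * (b / pb_sc) ** 2
            grad[1 + j] += -b / pb_sc**2
        if K > 0:
            gu2 = gu_sc * gu_sc
            uu = 0.0
            for j in range(K):
                uu += u[j] * u[j]
            lp += -0.5 * uu / gu2
            for j in range(Km1):
                grad[iv + j] += (-u[j] + u[K - 1]) / gu2
        sigma = np.exp(log_sigma)
        lp += -0.5 * (sigma / ps_sc) ** 2 + log_sigma
        grad[ils] += -((sigma / ps_sc) ** 2) + 1.0
        if not np.isfinite(lp):
            return -np.inf, grad
        return lp, grad

    @_njit(cache=True, error_model="numpy")
    def _bin_kernel(theta, X, k, ntot, codes, K, pa_loc, pa_sc, pb_loc, pb_sc, gu_sc, const_sum):
        d = theta.shape[0]
        n = k.shape[0]
        nb = X.shape[1]
        grad = np.zeros(d)
        for i in range(d):
            t = theta[i]
            if not np.isfinite(t) or abs(t) > 1e8:
                return -np.inf, grad
        alpha = theta[0]
        iv = 1 + nb
        Km1 = K - 1 if K > 0 else 0
        u = np.zeros(K + 1)
        if K > 0:
            ssum = 0.0
            for j in range(Km1):
                u[j] = theta[iv + j]
                ssum += u[j]
            u[K - 1] = -ssum
        du = np.zeros(K + 1)
        lp = const_sum
        ga = 0.0
        for i in range(n):
            eta = alpha
            for j in range(nb):
                eta += X[i, j] * theta[1 + j]
            if K > 0:
                eta += u[codes[i]]
            if eta > 0.0:
                softplus = eta + np.log1p(np.exp(-eta))
                p = 1.0 / (1.0 + np.exp(-eta))
            else:
                e = np.exp(eta)
                softplus = np.log1p(e)
                p = e / (1.0 + e)
            lp += k[i] * eta - ntot[i] * softplus
            de = k[i] - ntot[i] * p
            ga += de
            for j in range(nb):
                grad[1 + j] += X[i, j] * de
            if K > 0:
                du[codes[i]] += de
        grad[0] = ga
        for j in range(Km1):
            grad[iv + j] += du[j] - du[K - 1]
        lp += -0.5 * ((alpha - pa_loc) / pa_sc) ** 2
        grad[0] += -(alpha - pa_loc) / pa_sc**2
        for j in range(nb):
            b = theta[1 + j] - pb_loc
            lp += -0.5 * (b / pb_sc) ** 2
            grad[1 + j] += -b / pb_sc**2
        if K > 0:
            gu2 = gu_sc * gu_sc
            uu = 0.0
            for j in range(K):
                uu += u[j] * u[j]
            lp += -0.5 * uu / gu2
            for j in range(Km1):
                grad[iv + j] += (-u[j] + u[K - 1]) / gu2
        if not np.isfinite(lp):
            return -np.inf, grad
        return lp, grad


@dataclass(frozen=True)
class PriorSpec:
    """A normal or half-normal prior with location and scale."""

    distribution: str  # "normal" | "half_normal"
    location: float
    scale: float

    def __post_init__(self):
        if self.distribution not in ("normal", "half_normal"):
            raise ValueError(f"unknown prior distribution {self.distribution!r}")
        if not self.scale > 0:
            raise ValueError("prior scale must be positive")

    def to_dict(self) -> dict:
        return {"distribution": self.distribution, "location": self.location, "scale": self.scale}


def default_priors(table: MeasurementTable, family: str) -> dict[str, PriorSpec]:
    """Broad data-dependent default priors on the link scale.

    lognormal: with ``s = 10 * sd(log y) + 1``, alpha ~ Normal(mean(log y), s),
    effects and group intercepts ~ Normal(0, s), sigma ~ HalfNormal(0, s).
    binomial_logit: alpha ~ Normal(logit(pooled rate clipped to [0.01, 0.99]), 5),
    effects and group intercepts ~ Normal(0, 5).

    Every scale strictly exceeds the empirical spread of the data on the link
    scale, so the posterior is dominated by the likelihood.
    """
    if table.n < 2:
        raise ValueError("need at least 2 records to set default priors")
    if family == "lognormal":
        logy = np.log(table.response().astype(float))
        s = 10.0 * float(np.std(logy, ddof=1)) + 1.0
        return {
            "alpha": PriorSpec("normal", float(np.mean(logy)), s),
            "beta": PriorSpec("normal", 0.0, s),
            "u": PriorSpec("normal", 0.0, s),
            "sigma": PriorSpec("half_normal", 0.0, s),
        }
    if family == "binomial_logit":
        rate = table.response().sum() / table.totals().sum()
        rate = float(np.clip(rate, 0.01, 0.99))
        loc = float(np.log(rate / (1.0 - rate)))
        return {
            "alpha": PriorSpec("normal", loc, 5.0),
            "beta": PriorSpec("normal", 0.0, 5.0),
            "u": PriorSpec("normal", 0.0, 5.0),
        }
    raise SchemaError(f"unknown family {family!r}")


@dataclass
class _GroupBlock:
    factor: str
    levels: list
    codes: np.ndarray  # per-observation level index
    prior: PriorSpec


@dataclass
class ModelSpec:
    """A fully resolved model: families, terms, priors — serializable."""

    family: str
    parameters: list[dict]  # {name, role, prior}
    design_plan: dict

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "parameters": [
                {**p, "prior": p["prior"].to_dict() if isinstance(p["prior"], PriorSpec) else p["prior"]}
                for p in self.parameters
            ],
            "design_plan": self.design_plan,
        }


class BayesGLM:
    """A hierarchical GLM for one measurement table under one study design.

    Parameters
    ----------
    table : MeasurementTable
    design : StudyDesign
    priors : dict, optional
        Mapping with keys ``alpha``, ``beta``, ``u`` (and ``sigma`` for the
        lognormal family) to :class:`PriorSpec`; defaults to
        :func:`default_priors`.
    effect_of_interest : str, optional
        Name of the coefficient whose sign is reported by default.  For a
        three-level genotype this defaults to the hom-vs-control coefficient.
    pooled_group_intercepts : bool
        If True, group intercepts get a hierarchical scale (partial pooling)
        instead of the fixed broad prior.  Not the default.
    """

    def __init__(
        self,
        table: MeasurementTable,
        design: StudyDesign,
        priors: dict[str, PriorSpec] | None = None,
        effect_of_interest: str | None = None,
        pooled_group_intercepts: bool = False,
    ):
        report = validate_against_design(table, design)
        if not report.ok:
            raise SchemaError("table does not satisfy the design:\n" + report.text())
        self.table = table
        self.design = design
        self.family = design.family
        self.pooled = bool(pooled_group_intercepts)
        self.priors = dict(priors) if priors is not None else default_priors(table, self.family)

        # --- effect design matrix (treatment coding, reference = first level)
        cols: list[np.ndarray] = []
        names: list[str] = []
        term_cols: dict[str, list[int]] = {}
        for term in design.effect_terms:
            levels = table.factor_levels[term]
            codes = table.codes(term)
            term_cols[term] = []
            for j, lvl in enumerate(levels[1:], start=1):
                cols.append((codes == j).astype(float))
                term_cols[term].append(len(names))
                names.append(f"{term}[{lvl}]")
        if design.interaction:
            a, b = design.effect_terms[0], design.effect_terms[1]
            for ia in term_cols[a]:
                for ib in term_cols[b]:
                    cols.append(cols[ia] * cols[ib])
                    names.append(f"{names[ia]}:{names[ib]}")
        self.X = np.column_stack(cols) if cols else np.empty((table.n, 0))
        self.beta_names = names
        self.interaction_names = [n for n in names if ":" in n]

        # --- group intercept blocks
        self.groups: list[_GroupBlock] = []
        for f in design.group_intercept_factors:
            self.groups.append(
                _GroupBlock(
                    factor=f,
                    levels=table.factor_levels[f],
                    codes=table.codes(f),
                    prior=self.priors["u"],
                )
            )

        # --- responses
        if self.family == "lognormal":
            self.z = np.log(table.response().astype(float))
            self._logy_sum = float(self.z.sum())
        else:
            self.k = table.response().astype(float)
            self.ntot = table.totals().astype(float)
            self._binom_const = gammaln(self.ntot + 1) - gammaln(self.k + 1) - gammaln(self.ntot - self.k + 1)

        # --- sampling-space layout: alpha | beta | per-factor v (K-1) [| log_tau] | log_sigma
        self._segments: list[tuple[str, int]] = [("alpha", 1), ("beta", self.X.shape[1])]
        for g in self.groups:
            self._segments.append((f"v_{g.factor}", len(g.levels) - 1))
            if self.pooled:
                self._segments.append((f"log_tau_{g.factor}", 1))
        if self.family == "lognormal":
            self._segments.append(("log_sigma", 1))
        self.n_dim = sum(n for _, n in self._segments)

        if effect_of_interest is None:
            effect_of_interest = self._default_effect_of_interest()
        self.effect_of_interest = effect_of_interest

        # --- precomputation for the sampling hot path (non-pooled layout)
        self._nb = self.X.shape[1]
        self._XT = np.ascontiguousarray(self.X.T)
        pos = 1 + self._nb
        self._gfast = []
        for g in self.groups:
            K = len(g.levels)
            self._gfast.append((slice(pos, pos + K - 1), g.codes, K, g.prior.scale**2))
            pos += K - 1
            if self.pooled:
                pos += 1
        if self.family == "binomial_logit":
            self._binom_const_sum = float(self._binom_const.sum())
        self._use_kernel = _HAVE_NUMBA and not self.pooled and len(self.groups) <= 1
        if self._use_kernel:
            self._Xc = np.ascontiguousarray(self.X, dtype=np.float64)
            if self.groups:
                self._kcodes = np.ascontiguousarray(self.groups[0].codes, dtype=np.int64)
                self._K = len(self.groups[0].levels)
                self._gu_sc = float(self.groups[0].prior.scale)
            else:
                self._kcodes = np.zeros(0, dtype=np.int64)
                self._K = 0
                self._gu_sc = 1.0

    # ------------------------------------------------------------------ #
    def _default_effect_of_interest(self) -> str | None:
        if not self.beta_names:
            return None
        term = self.design.effect_terms[0]
        hom = f"{term}[hom]"
        if hom in self.beta_names:
            return hom
        for n in self.beta_names:
            if n.startswith(f"{term}[") and ":" not in n:
                return n
        return self.beta_names[0]

    # ------------------------------------------------------------------ #
    def _unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        out, i = {}, 0
        for name, n in self._segments:
            out[name] = theta[..., i : i + n]
            i += n
        return out

    @staticmethod
    def _full_u(v: np.ndarray) -> np.ndarray:
        """Append the sum-to-zero level: u = [v_1..v_{K-1}, -sum v]."""
        return np.concatenate([v, -v.sum(axis=-1, keepdims=True)], axis=-1)

    def _eta(self, parts: dict[str, np.ndarray]) -> np.ndarray:
        eta = parts["alpha"][..., 0, None] + parts["beta"] @ self.X.T
        for g in self.groups:
            u = self._full_u(parts[f"v_{g.factor}"])
            eta = eta + u[..., g.codes]
        return eta

    # ------------------------------------------------------------------ #
    # log posterior and gradient in the sampling space (used by the HMC core)
    def logpost_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            if self._use_kernel:
                pa, pb = self.priors["alpha"], self.priors["beta"]
                if self.family == "lognormal":
                    lp, grad = _ln_kernel(
                        theta, self._Xc, self.z, self._kcodes, self._K,
                        pa.location, pa.scale, pb.location, pb.scale,
                        self._gu_sc, self.priors["sigma"].scale, self._logy_sum,
                    )
                else:
                    lp, grad = _bin_kernel(
                        theta, self._Xc, self.k, self.ntot, self._kcodes, self._K,
                        pa.location, pa.scale, pb.location, pb.scale,
                        self._gu_sc, self._binom_const_sum,
                    )
                return float(lp), grad
            if self.pooled:
                return self._logpost_and_grad_general(theta)
            return self._logpost_and_grad_fast(theta)

    def _logpost_and_grad_fast(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Streamlined log posterior + gradient for the fixed-intercept layout."""
        if not np.all(np.isfinite(theta)) or np.any(np.abs(theta) > 1e8):
            return -np.inf, np.zeros_like(theta)
        nb = self._nb
        alpha = theta[0]
        beta = theta[1 : 1 + nb]
        eta = alpha + (self.X @ beta if nb else 0.0)
        if not self._gfast and nb == 0:
            eta = np.full(self.table.n, alpha)
        u_cache = []
        for sl, codes, K, _ in self._gfast:
            v = theta[sl]
            u = np.empty(K)
            u[: K - 1] = v
            u[K - 1] = -v.sum()
            u_cache.append(u)
            eta = eta + u[codes]

        grad = np.zeros_like(theta)
        if self.family == "lognormal":
            log_sigma = min(theta[-1], 300.0)
            sigma2 = np.exp(2.0 * log_sigma)
            r = self.z - eta
            rss = float(r @ r)
            lp = -0.5 * rss / sigma2 - self.table.n * (log_sigma + 0.5 * _LOG2PI) - self._logy_sum
            deta = r / sigma2
            grad[-1] = rss / sigma2 - self.table.n
        else:
            theta_p = expit(eta)
            lp = float(self.k @ eta - self.ntot @ np.logaddexp(0.0, eta)) + self._binom_const_sum
            deta = self.k - self.ntot * theta_p

        grad[0] = deta.sum()
        if nb:
            grad[1 : 1 + nb] = self._XT @ deta
        for (sl, codes, K, _), u in zip(self._gfast, u_cache):
            du = np.bincount(codes, weights=deta, minlength=K)
            grad[sl] += du[: K - 1] - du[K - 1]

        pa = self.priors["alpha"]
        lp -= 0.5 * (alpha - pa.location) ** 2 / pa.scale**2
        grad[0] -= (alpha - pa.location) / pa.scale**2
        if nb:
            pb = self.priors["beta"]
            db = beta - pb.location
            lp -= 0.5 * float(db @ db) / pb.scale**2
            grad[1 : 1 + nb] -= db / pb.scale**2
        for (sl, codes, K, sc2), u in zip(self._gfast, u_cache):
            lp -= 0.5 * float(u @ u) / sc2
            gu = -u / sc2
            grad[sl] += gu[: K - 1] - gu[K - 1]
        if self.family == "lognormal":
            ps = self.priors["sigma"]
            sigma = np.exp(log_sigma)
            lp += -0.5 * (sigma / ps.scale) ** 2 + log_sigma
            grad[-1] += -((sigma / ps.scale) ** 2) + 1.0

        if not np.isfinite(lp):
            return -np.inf, grad
        return float(lp), grad

    def _logpost_and_grad_general(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        if not np.all(np.isfinite(theta)) or np.any(np.abs(theta) > 1e8):
            return -np.inf, np.zeros_like(theta)
        parts = self._unpack(theta)
        alpha = parts["alpha"][0]
        beta = parts["beta"]
        eta = alpha + self.X @ beta
        for g in self.groups:
            u = self._full_u(parts[f"v_{g.factor}"])
            eta = eta + u[g.codes]

        grad = np.zeros_like(theta)
        gparts = self._unpack(grad)  # views into grad

        if self.family == "lognormal":
            sigma = np.exp(np.minimum(parts["log_sigma"][0], 300.0))
            r = (self.z - eta) / sigma**2
            lp = (
                -0.5 * np.sum((self.z - eta) ** 2) / sigma**2
                - self.table.n * (np.log(sigma) + 0.5 * _LOG2PI)
                - self._logy_sum
            )
            deta = r
            gparts["log_sigma"][0] += np.sum((self.z - eta) ** 2) / sigma**2 - self.table.n
        else:
            theta_p = expit(eta)
            lp = float(np.sum(self.k * eta - self.ntot * np.logaddexp(0.0, eta) + self._binom_const))
            deta = self.k - self.ntot * theta_p

        gparts["alpha"][0] += deta.sum()
        if self.X.shape[1]:
            gparts["beta"][...] += self.X.T @ deta
        for g in self.groups:
            du = np.bincount(g.codes, weights=deta, minlength=len(g.levels))
            gparts[f"v_{g.factor}"][...] += du[:-1] - du[-1]

        # ---- priors
        pa = self.priors["alpha"]
        lp += -0.5 * ((alpha - pa.location) / pa.scale) ** 2
        gparts["alpha"][0] += -(alpha - pa.location) / pa.scale**2
        pb = self.priors["beta"]
        if beta.size:
            lp += -0.5 * np.sum((beta - pb.location) ** 2) / pb.scale**2
            gparts["beta"][...] += -(beta - pb.location) / pb.scale**2
        for g in self.groups:
            u = self._full_u(parts[f"v_{g.factor}"])
            if self.pooled:
                log_tau = parts[f"log_tau_{g.factor}"][0]
                tau = np.exp(np.minimum(log_tau, 300.0))
                K = len(g.levels)
                lp += -0.5 * np.sum(u**2) / tau**2 - K * np.log(tau)
                gu = -u / tau**2
                # half-normal hyperprior on tau (scale from the broad u prior) + log Jacobian
                lp += -0.5 * (tau / g.prior.scale) ** 2 + log_tau
                gparts[f"log_tau_{g.factor}"][0] += np.sum(u**2) / tau**2 - K - (tau / g.prior.scale) ** 2 + 1.0
            else:
                lp += -0.5 * np.sum(u**2) / g.prior.scale**2
                gu = -u / g.prior.scale**2
            gparts[f"v_{g.factor}"][...] += gu[:-1] - gu[-1]
        if self.family == "lognormal":
            ps = self.priors["sigma"]
            log_sigma = parts["log_sigma"][0]
            sigma = np.exp(np.minimum(log_sigma, 300.0))
            lp += -0.5 * (sigma / ps.scale) ** 2 + log_sigma  # half-normal + Jacobian
            gparts["log_sigma"][0] += -((sigma / ps.scale) ** 2) + 1.0

        if not np.isfinite(lp):
            return -np.inf, grad
        return float(lp), grad

    # ------------------------------------------------------------------ #
    def initial_points(self, chains: int, rng: np.random.Generator) -> np.ndarray:
        """Data-informed starting points with per-chain jitter."""
        x0 = np.zeros(self.n_dim)
        parts = self._unpack(x0)
        if self.family == "lognormal":
            parts["alpha"][0] = float(np.mean(self.z))
            sd = float(np.std(self.z, ddof=1)) if self.table.n > 1 else 0.5
            parts["log_sigma"][0] = np.log(max(sd, 1e-3))
        else:
            rate = np.clip(self.k.sum() / self.ntot.sum(), 0.01, 0.99)
            parts["alpha"][0] = float(np.log(rate / (1 - rate)))
        pts = x0[None, :] + 0.1 * rng.standard_normal((chains, self.n_dim))
        return pts

    # ------------------------------------------------------------------ #
    # reported-parameter space: alpha, beta..., u_f[level]..., (tau_f,) (sigma)
    @property
    def param_names(self) -> list[str]:
        names = ["alpha"] + list(self.beta_names)
        for g in self.groups:
            names += [f"u_{g.factor}[{lvl}]" for lvl in g.levels]
            if self.pooled:
                names.append(f"tau_{g.factor}")
        if self.family == "lognormal":
            names.append("sigma")
        return names

    def to_reported(self, theta: np.ndarray) -> np.ndarray:
        """Map sampling-space draws (..., n_dim) to reported parameters."""
        parts = self._unpack(np.asarray(theta, dtype=float))
        out = [parts["alpha"], parts["beta"]]
        for g in self.groups:
            out.append(self._full_u(parts[f"v_{g.factor}"]))
            if self.pooled:
                out.append(np.exp(parts[f"log_tau_{g.factor}"]))
        if self.family == "lognormal":
            out.append(np.exp(parts["log_sigma"]))
        return np.concatenate(out, axis=-1)

    # ------------------------------------------------------------------ #
    def eta_from_params(self, params: dict[str, float]) -> np.ndarray:
        """Linear predictor for every observation from named parameters."""
        eta = np.full(self.table.n, float(params["alpha"]))
        for j, name in enumerate(self.beta_names):
            eta += float(params[name]) * self.X[:, j]
        for g in self.groups:
            u = np.array([float(params[f"u_{g.factor}[{lvl}]"]) for lvl in g.levels])
            eta += u[g.codes]
        return eta

    def pointwise_log_likelihood(self, params: dict[str, float], i: int | None = None):
        """Log-likelihood of observation ``i`` (or all) at named parameters.

        For the lognormal family this is the density of y itself (normal
        density of log y plus the -log y Jacobian); for the binomial family
        the full binomial pmf.  A success probability pinned to exactly 0 or
        1 with incompatible counts yields ``-inf``, not an exception.
        """
        eta = self.eta_from_params(params)
        if self.family == "lognormal":
            sigma = float(params["sigma"])
            ll = -0.5 * ((self.z - eta) / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI - self.z
        else:
            p = expit(eta)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = self._binom_const + xlogy(self.k, p) + xlogy(self.ntot - self.k, 1.0 - p)
            ll = np.where(np.isnan(ll), -np.inf, ll)
        return ll if i is None else float(ll[i])

    def loglik_matrix(self, reported_draws: np.ndarray) -> np.ndarray:
        """Pointwise log-likelihood, (n_draws, n_obs), from reported draws."""
        names = self.param_names
        idx = {n: j for j, n in enumerate(names)}
        draws = np.asarray(reported_draws, dtype=float)
        alpha = draws[:, idx["alpha"]]
        eta = alpha[:, None] + np.zeros((draws.shape[0], self.table.n))
        for j, name in enumerate(self.beta_names):
            eta += draws[:, idx[name]][:, None] * self.X[None, :, j]
        for g in self.groups:
            u = draws[:, [idx[f"u_{g.factor}[{lvl}]"] for lvl in g.levels]]
            eta += u[:, g.codes]
        if self.family == "lognormal":
            sigma = draws[:, idx["sigma"]][:, None]
            return -0.5 * ((self.z[None, :] - eta) / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG2PI - self.z[None, :]
        p = expit(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = self._binom_const[None, :] + xlogy(self.k[None, :], p) + xlogy((self.ntot - self.k)[None, :], 1.0 - p)
        return np.where(np.isnan(ll), -np.inf, ll)

    # ------------------------------------------------------------------ #
    def spec(self) -> ModelSpec:
        """Serializable description of the resolved model (for provenance)."""
        params: list[dict] = [{"name": "alpha", "role": "global_intercept", "prior": self.priors["alpha"]}]
        for n in self.beta_names:
            role = "interaction" if ":" in n else "effect"
            params.append({"name": n, "role": role, "prior": self.priors["beta"]})
        for g in self.groups:
            for lvl in g.levels:
                params.append({"name": f"u_{g.factor}[{lvl}]", "role": "group_intercept", "prior": g.prior})
        if self.family == "lognormal":
            params.append({"name": "sigma", "role": "noise_sd", "prior": self.priors["sigma"]})
        return ModelSpec(
            family=self.family,
            parameters=params,
            design_plan={
                "effect_terms": list(self.design.effect_terms),
                "interaction": self.design.interaction,
                "group_intercept_factors": [g.factor for g in self.groups],
                "sum_to_zero_group_intercepts": not self.pooled,
                "effect_of_interest": self.effect_of_interest,
            },
        )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(cls, df, design: StudyDesign, **kwargs) -> "BayesGLM":
        """Build a model straight from a tidy DataFrame."""
        table = MeasurementTable(df, kind=design.response_kind)
        return cls(table, design, **kwargs)

    def fit(self, config=None, **kwargs):
        """Sample the posterior; returns a :class:`BayesGLMResults`."""
        from .results import BayesGLMResults
        from .sampler import SamplerConfig, sample_posterior_raw

        if config is None:
            config = SamplerConfig(**kwargs)
        raw, stats = sample_posterior_raw(self, config)
        reported = self.to_reported(raw)
        return BayesGLMResults(self, reported, self.param_names, config, stats)
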