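"""Model construction: design matrices, priors, pointwise log-likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

from chondrofit import BayesGLM, MeasurementTable, StudyDesign, default_priors
from chondrofit.data import SchemaError
from tests.conftest import two_group_binomial, two_group_lognormal


class TestStructure:
    def test_length_model_parameters(self, length_table, lognormal_design):
        m = BayesGLM(length_table, lognormal_design)
        assert m.param_names == [
            "alpha",
            "genotype[hom]",
            "u_litter[L1]",
            "u_litter[L2]",
            "sigma",
        ]
        assert m.effect_of_interest == "genotype[hom]"

    def test_interaction_model_parameters(self):
        from chondrofit import simulate_explant_study

        ds = simulate_explant_study(n_embryos_per_genotype=(3, 3), seed=0)
        m = BayesGLM(ds.table, ds.design)
        assert "genotype[hom]" in m.param_names
        assert "treatment[purmorphamine]" in m.param_names
        assert "genotype[hom]:treatment[purmorphamine]" in m.param_names
        assert all(not n.startswith("sigma") for n in m.param_names)  # binomial: no sigma
        assert any(n.startswith("u_animal[") for n in m.param_names)

    def test_three_level_genotype_yields_two_coefficients(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "value": np.exp(rng.normal(8, 0.1, 9)),
                "genotype": ["control", "het", "hom"] * 3,
                "litter": ["L1", "L2", "L3"] * 3,
            }
        )
        m = BayesGLM(MeasurementTable(df, kind="continuous"), StudyDesign(family="lognormal"))
        assert {"genotype[het]", "genotype[hom]"} <= set(m.param_names)
        assert m.effect_of_interest == "genotype[hom]"  # hom-vs-control is the default

    def test_design_table_mismatch_raises(self, length_table):
        d = StudyDesign(family="binomial_logit", effect_terms=["genotype"])
        with pytest.raises(SchemaError):
            BayesGLM(length_table, d)

    def test_sum_to_zero_constraint_in_reported_draws(self, length_table, lognormal_design):
        m = BayesGLM(length_table, lognormal_design)
        theta = np.random.default_rng(0).normal(size=m.n_dim)
        rep = m.to_reported(theta)
        i1 = m.param_names.index("u_litter[L1]")
        i2 = m.param_names.index("u_litter[L2]")
        assert rep[i1] + rep[i2] == pytest.approx(0.0, abs=1e-12)

    def test_spec_serialization_lists_roles_and_priors(self, length_table, lognormal_design):
        spec = BayesGLM(length_table, lognormal_design).spec()
        roles = {p["name"]: p["role"] for p in spec.to_dict()["parameters"]}
        assert roles["alpha"] == "global_intercept"
        assert roles["genotype[hom]"] == "effect"
        assert roles["sigma"] == "noise_sd"
        assert roles["u_litter[L1]"] == "group_intercept"


class TestPriors:
    def test_lognormal_scale_formula(self):
        # construct data with sd(log y) = 0.1 exactly -> effect prior scale 2.0
        z = np.array([-0.1, 0.1]) / np.sqrt(2) * np.sqrt(2)  # sd (ddof=1) of +-0.1/sqrt... build directly
        z = np.array([0.0, 0.1 * np.sqrt(2)])  # ddof=1 sd = 0.1
        df = pd.DataFrame({"value": np.exp(z), "genotype": ["control", "hom"], "litter": ["L1", "L1"]})
        priors = default_priors(MeasurementTable(df, kind="continuous"), "lognormal")
        assert priors["beta"].scale == pytest.approx(2.0)
        assert priors["sigma"].distribution == "half_normal"

    def test_binomial_alpha_location_is_logit_of_pooled_rate(self):
        df = pd.DataFrame(
            {"labelled": [15, 15], "total": [100, 100], "genotype": ["control", "hom"], "litter": ["L1", "L1"]}
        )
        priors = default_priors(MeasurementTable(df, kind="count"), "binomial_logit")
        assert priors["alpha"].location == pytest.approx(-1.7346, abs=1e-4)
        assert priors["alpha"].scale == 5.0

    def test_single_record_table_rejected(self):
        df = pd.DataFrame({"value": [1.0], "genotype": ["control"], "litter": ["L1"]})
        with pytest.raises(ValueError):
            default_priors(MeasurementTable(df, kind="continuous"), "lognormal")

    def test_prior_scales_exceed_data_spread_on_link_scale(self, length_table):
        priors = default_priors(length_table, "lognormal")
        spread = np.std(np.log(length_table.response()), ddof=1)
        for key in ("alpha", "beta", "u", "sigma"):
            assert priors[key].scale > spread


class TestPointwiseLogLikelihood:
    def test_binomial_closed_form(self):
        t = two_group_binomial(0)
        t.df.loc[0, "labelled"] = 1
        t.df.loc[0, "total"] = 2
        t2 = MeasurementTable(t.df, kind="count")
        m = BayesGLM(t2, StudyDesign(family="binomial_logit", effect_terms=["genotype"]))
        params = {"alpha": 0.0, "genotype[hom]": 0.0}
        # total=2, labelled=1, theta=0.5 -> log(2 * 0.25) = log 0.5... C(2,1)=2
        assert m.pointwise_log_likelihood(params, 0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_lognormal_standard_normal_at_mode(self):
        df = pd.DataFrame({"value": [1.0, 2.0], "genotype": ["control", "hom"], "litter": ["L1", "L1"]})
        m = BayesGLM(
            MeasurementTable(df, kind="continuous"),
            StudyDesign(family="lognormal", effect_terms=["genotype"]),
        )
        params = {"alpha": 0.0, "genotype[hom]": 0.0, "sigma": 1.0}
        assert m.pointwise_log_likelihood(params, 0) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_binomial_matches_scipy_for_arbitrary_eta(self):
        t = two_group_binomial(1)
        m = BayesGLM(t, StudyDesign(family="binomial_logit", effect_terms=["genotype"]))
        params = {"alpha": -1.0, "genotype[hom]": 0.3}
        eta = m.eta_from_params(params)
        expected = stats.binom.logpmf(m.k, m.ntot, expit(eta))
        np.testing.assert_allclose(m.pointwise_log_likelihood(params), expected, rtol=1e-10)

    def test_binomial_saturated_theta_gives_neg_inf_not_exception(self):
        df = pd.DataFrame(
            {"labelled": [3, 5], "total": [10, 10], "genotype": ["control", "hom"], "litter": ["L1", "L1"]}
        )
        m = BayesGLM(
            MeasurementTable(df, kind="count"),
            StudyDesign(family="binomial_logit", effect_terms=["genotype"]),
        )
        ll = m.pointwise_log_likelihood({"alpha": 800.0, "genotype[hom]": 0.0}, 0)  # theta -> 1, labelled < total
        assert ll == -np.inf

    def test_binomial_normalization_by_enumeration(self):
        """Summing the pmf over labelled = 0..total gives exactly 1."""
        base = {"labelled": [0], "total": [7], "genotype": ["control"], "litter": ["L1"]}
        probs = []
        for k in range(8):
            df = pd.DataFrame({**base, "labelled": [k], "genotype": ["control"]})
            df2 = pd.DataFrame(
                {
                    "labelled": [k, 1],
                    "total": [7, 10],
                    "genotype": ["control", "hom"],
                    "litter": ["L1", "L1"],
                }
            )
            m = BayesGLM(
                MeasurementTable(df2, kind="count"),
                StudyDesign(family="binomial_logit", effect_terms=["genotype"]),
            )
            probs.append(np.exp(m.pointwise_log_likelihood({"alpha": -0.7, "genotype[hom]": 0.2}, 0)))
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_lognormal_density_integrates_to_one(self):
        t = two_group_lognormal(2)
        m = BayesGLM(t, StudyDesign(family="lognormal", effect_terms=["genotype"]))
        params = {"alpha": 0.0, "genotype[hom]": -0.1, "sigma": 0.3}

        def dens(y):
            mm = BayesGLM(
                MeasurementTable(
                    pd.DataFrame(
                        {"value": [y, 1.0], "genotype": ["control", "hom"], "animal": ["A1", "A2"]}
                    ),
                    kind="continuous",
                ),
                StudyDesign(family="lognormal", effect_terms=["genotype"]),
                priors=m.priors,
            )
            return np.exp(mm.pointwise_log_likelihood(params, 0))

        total, _ = integrate.quad(dens, 1e-4, 15.0, limit=200)  # density centred at y = e^0 = 1
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_loglik_matrix_agrees_with_pointwise(self, length_table, lognormal_design):
        m = BayesGLM(length_table, lognormal_design)
        rng = np.random.default_rng(3)
        theta = rng.normal(size=(5, m.n_dim)) * 0.05
        theta[:, 0] = 8.5
        rep = m.to_reported(theta)
        mat = m.loglik_matrix(rep)
        for s in range(5):
            params = dict(zip(m.param_names, rep[s]))
            np.testing.assert_allclose(mat[s], m.pointwise_log_likelihood(params), rtol=1e-10)


def test_jit_kernel_matches_reference_log_posterior_and_gradient():
    """The accelerated log-posterior kernels agree with the plain-numpy
    reference implementation, and the gradient matches finite differences."""
    from chondrofit import (
        simulate_brdu_study,
        simulate_explant_study,
        simulate_length_study,
    )

    rng = np.random.default_rng(7)
    for ds in (simulate_length_study(seed=3), simulate_brdu_study(seed=4), simulate_explant_study(seed=5)):
        m = BayesGLM(ds.table, ds.design)
        for _ in range(3):
            theta = rng.normal(size=m.n_dim) * 0.3
            if m.family == "lognormal":
                theta[0] = rng.normal(3, 2)
                theta[-1] = rng.normal(-2, 0.5)
            lp, g = m.logpost_and_grad(theta)
            lp_ref, g_ref = m._logpost_and_grad_general(theta)
            assert lp == pytest.approx(lp_ref, rel=1e-10)
            np.testing.assert_allclose(g, g_ref, atol=1e-8)
            num = np.empty_like(theta)
            for i in range(len(theta)):
                e = np.zeros_like(theta)
                e[i] = 1e-6
                num[i] = (m.logpost_and_grad(theta + e)[0] - m.logpost_and_grad(theta - e)[0]) / 2e-6
            np.testing.assert_allclose(g, num, atol=5e-4)


def test_rescaling_values_shifts_only_alpha_in_flat_prior_limit():
    """Multiplying all lengths by c moves alpha's posterior by log c, not beta's."""
    from chondrofit import SamplerConfig

    t1 = two_group_lognormal(7, n0=6, n1=6, beta=-0.1)
    df2 = t1.df.copy()
    df2["value"] = df2["value"] * 10.0
    t2 = MeasurementTable(df2, kind="continuous")
    d = StudyDesign(family="lognormal", effect_terms=["genotype"])
    cfg = SamplerConfig(chains=2, iterations=800, warmup=400, seed=5)
    r1 = BayesGLM(t1, d).fit(cfg)
    r2 = BayesGLM(t2, d).fit(cfg)
    assert np.mean(r2.get("alpha")) - np.mean(r1.get("alpha")) == pytest.approx(np.log(10), abs=0.02)
    assert np.mean(r2.get("genotype[hom]")) == pytest.approx(np.mean(r1.get("genotype[hom]")), abs=0.02)
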