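"""Posterior predictive checks and leave-one-out cross-validation."""

import numpy as np
import pytest

from chondrofit import (
    BayesGLM,
    SamplerConfig,
    StudyDesign,
    compare_interaction_models,
    posterior_predictive_replicates,
    ppc_pvalue,
    ppc_summary,
    psis_loo,
    simulate_explant_study,
)
from chondrofit.compare import LooResult
from chondrofit.data import SchemaError


class TestPpc:
    def test_pvalue_at_median(self):
        assert ppc_pvalue(5.0, [1, 2, 3, 4, 5, 6, 7, 8, 9]) == pytest.approx(5 / 9)

    def test_observed_above_all_replicates_inconsistent(self):
        assert ppc_pvalue(100.0, [1.0, 2.0]) == 0.0

    def test_observed_below_all_replicates_inconsistent(self):
        assert ppc_pvalue(-100.0, [1.0, 2.0]) == 1.0

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            ppc_pvalue(1.0, [])

    def test_nrep_validation(self, length_table, lognormal_design, fast_config):
        res = BayesGLM(length_table, lognormal_design).fit(fast_config)
        with pytest.raises(ValueError):
            posterior_predictive_replicates(res, 0)

    def test_lognormal_replicates_positive(self, length_table, lognormal_design, fast_config):
        res = BayesGLM(length_table, lognormal_design).fit(fast_config)
        reps = posterior_predictive_replicates(res, 50, seed=1)
        assert reps.shape == (50, length_table.n)
        assert np.all(reps > 0)

    def test_binomial_saturated_alpha_labels_everything(self, count_table, binomial_design, fast_config):
        res = BayesGLM(count_table, binomial_design).fit(fast_config)
        res.draws[:, :, res.param_names.index("alpha")] = 50.0  # theta -> 1
        for name in res.param_names[1:]:
            res.draws[:, :, res.param_names.index(name)] = 0.0
        reps = posterior_predictive_replicates(res, 20, seed=2)
        np.testing.assert_array_equal(reps, np.broadcast_to(res.model.ntot, reps.shape))

    def test_self_consistency_for_model_generated_data(self, fast_config):
        """Data drawn from the model itself passes its own PPC."""
        from chondrofit import simulate_length_study

        ds = simulate_length_study(seed=17)
        res = BayesGLM(ds.table, ds.design).fit(fast_config)
        checks = ppc_summary(res, n_rep=300, seed=3)
        names = {c.statistic_name for c in checks}
        assert {"mean", "sd", "min", "max", "group_mean[control]", "group_mean[hom]"} <= names
        mean_check = next(c for c in checks if c.statistic_name == "mean")
        assert mean_check.consistent


class TestPsisLoo:
    def test_identical_models_have_zero_elpd_diff(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-1, 0.3, size=(400, 12))
        a, b = psis_loo(ll), psis_loo(ll.copy())
        assert a.elpd == pytest.approx(b.elpd)
        diff = a.pointwise_elpd - b.pointwise_elpd
        assert np.allclose(diff, 0.0)

    def test_elpd_is_sum_of_pointwise(self):
        rng = np.random.default_rng(1)
        loo = psis_loo(rng.normal(-2, 0.5, size=(300, 9)))
        assert loo.elpd == pytest.approx(float(np.nansum(loo.pointwise_elpd)))
        assert loo.se >= 0

    def test_all_neg_inf_column_flagged_and_excluded(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-1, 0.2, size=(200, 5))
        ll[:, 3] = -np.inf
        with pytest.warns(UserWarning):
            loo = psis_loo(ll)
        assert 3 in loo.flagged_points
        assert np.isfinite(loo.elpd)

    def test_well_specified_data_has_small_pareto_k(self):
        """Typical-case tail diagnostics: the occasional influential point is
        tolerated (that is what the exact-refit fallback is for), but the
        vast majority of Pareto-k values stay below 0.7."""
        from chondrofit import simulate_length_study

        ks = []
        for seed in (20, 21, 22):
            ds = simulate_length_study(seed=seed)
            res = BayesGLM(ds.table, ds.design).fit(
                SamplerConfig(chains=3, iterations=1200, warmup=600, seed=seed)
            )
            loo = psis_loo(res.loglik_matrix())
            assert loo.method == "psis"
            ks.extend(loo.pareto_k.tolist())
        assert np.mean(np.asarray(ks) < 0.7) >= 0.9


class TestInteractionComparison:
    def test_design_without_second_term_rejected(self, count_table):
        d = StudyDesign(family="binomial_logit", effect_terms=["genotype"])
        with pytest.raises(SchemaError):
            compare_interaction_models(count_table, d)

    def test_comparison_returns_decision_and_bookkeeping(self, fast_config):
        ds = simulate_explant_study(n_embryos_per_genotype=(5, 5), seed=9)
        cmp_ = compare_interaction_models(ds.table, ds.design, fast_config, require_convergence=False)
        assert cmp_.preferred in ("interaction", "no_interaction", "indistinguishable")
        assert cmp_.elpd_diff == pytest.approx(cmp_.elpd_interaction - cmp_.elpd_no_interaction, abs=1e-6)
        if abs(cmp_.elpd_diff) <= 2 * cmp_.diff_se:
            assert cmp_.preferred == "indistinguishable"
        d = cmp_.to_dict()
        assert "rule" in d and "pareto_k_max" in d


def test_loo_result_flagging_threshold():
    loo = LooResult(
        elpd=-10.0,
        se=1.0,
        pointwise_elpd=np.array([-5.0, -5.0]),
        pareto_k=np.array([0.2, 0.9]),
    )
    assert loo.flagged_points == [1]
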