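"""Synthetic-data generators: determinism, degenerate cases, closed forms."""

import numpy as np
import pytest
from scipy.special import expit, logit

from chondrofit import (
    simulate_brdu_study,
    simulate_explant_study,
    simulate_length_study,
    simulate_qpcr_study,
    validate_against_design,
)

GENERATORS = [
    (simulate_length_study, {}),
    (simulate_brdu_study, {}),
    (simulate_qpcr_study, {}),
    (simulate_explant_study, {}),
]


@pytest.mark.parametrize("gen,kwargs", GENERATORS)
def test_seed_determinism(gen, kwargs):
    a = gen(seed=123, **kwargs)
    b = gen(seed=123, **kwargs)
    assert a.table.df.equals(b.table.df)
    c = gen(seed=124, **kwargs)
    assert not a.table.df.equals(c.table.df)


@pytest.mark.parametrize("gen,kwargs", GENERATORS)
def test_generated_tables_pass_design_validation(gen, kwargs):
    ds = gen(seed=7, **kwargs)
    assert validate_against_design(ds.table, ds.design).ok


class TestLengthStudy:
    def test_degenerate_no_noise_all_equal(self):
        ds = simulate_length_study(genotype_multiplier=1.0, litter_sd=0.0, sigma=0.0, seed=1)
        assert np.allclose(ds.table.df["value"], 5000.0)

    def test_pure_multiplier_effect(self):
        ds = simulate_length_study(genotype_multiplier=0.865, litter_sd=0.0, sigma=0.0, seed=1)
        vals = ds.table.df
        control = vals[vals.genotype == "control"]["value"].iloc[0]
        mutant = vals[vals.genotype == "hom"]["value"].iloc[0]
        assert mutant / control == pytest.approx(0.865)
        assert ds.truth.effects["genotype[hom]"] == pytest.approx(np.log(0.865))

    def test_round_robin_litters_cross_genotype(self):
        ds = simulate_length_study(seed=2)
        per_litter = ds.table.df.groupby("litter")["genotype"].nunique()
        assert (per_litter == 2).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_length_study(genotype_multiplier=0.0)
        with pytest.raises(ValueError):
            simulate_length_study(control_geomean=-5.0)


class TestBrduStudy:
    def test_null_pooled_rates_agree(self):
        ds = simulate_brdu_study(rate_drop_pp=0.0, animal_sd=0.0, totals_range=(5000, 5000), seed=3)
        df = ds.table.df
        rates = df.groupby("genotype").apply(
            lambda g: g.labelled.sum() / g.total.sum(), include_groups=False
        )
        assert abs(rates["control"] - rates["hom"]) < 0.03  # binomial error at n=5000
        assert ds.truth.effects["genotype[hom]"] == 0.0

    def test_extreme_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_brdu_study(control_rate=1.0)

    def test_true_beta_is_logit_difference(self):
        ds = simulate_brdu_study(control_rate=0.30, rate_drop_pp=5.4, seed=4)
        assert ds.truth.effects["genotype[hom]"] == pytest.approx(logit(0.246) - logit(0.30))

    def test_counts_within_totals(self):
        ds = simulate_brdu_study(seed=5)
        df = ds.table.df
        assert ((df.labelled >= 0) & (df.labelled <= df.total)).all()


class TestQpcrStudy:
    def test_null_no_noise_all_equal(self):
        ds = simulate_qpcr_study(fold_change=1.0, batch_sd=0.0, sigma=0.0, seed=6)
        assert np.allclose(ds.table.df["value"], 0.05)

    def test_halving_fold_change_halves_geometric_mean(self):
        ds = simulate_qpcr_study(fold_change=0.5, batch_sd=0.0, sigma=0.0, seed=6)
        df = ds.table.df
        gm = df.groupby("genotype")["value"].apply(lambda v: np.exp(np.mean(np.log(v))))
        assert gm["hom"] / gm["control"] == pytest.approx(0.5)


class TestExplantStudy:
    def test_zero_interaction_equal_treatment_effect_across_genotypes(self):
        ds = simulate_explant_study(interaction_pp=0.0, seed=7)
        # on the probability scale the treatment effect is identical by construction
        # (the logit-scale interaction coefficient is then small but non-zero)
        a, bt, bg = ds.truth.alpha, ds.truth.effects["treatment[purmorphamine]"], ds.truth.effects["genotype[hom]"]
        bi = ds.truth.interaction
        control_boost = expit(a + bt) - expit(a)
        mutant_boost = expit(a + bg + bt + bi) - expit(a + bg)
        assert mutant_boost == pytest.approx(control_boost, abs=1e-12)

    def test_interaction_coefficient_closed_form(self):
        """With no embryo noise the logit-scale coefficients reproduce the cell rates."""
        ds = simulate_explant_study(
            control_rate=0.25, treatment_boost_pp=3.2, genotype_drop_pp=2.4, interaction_pp=-3.2, seed=8
        )
        tr = ds.truth
        # mutant treated cell: control - drop + boost + interaction = 0.25 - 0.024 + 0.032 - 0.032
        expected = logit(0.226) - logit(0.226)  # boost fully cancelled
        got = expit(tr.alpha + tr.effects["genotype[hom]"] + tr.effects["treatment[purmorphamine]"] + tr.interaction)
        assert got == pytest.approx(0.25 - 0.024 + 0.032 - 0.032, abs=1e-12)

    def test_two_records_per_embryo_sharing_intercept(self):
        ds = simulate_explant_study(seed=9)
        counts = ds.table.df.groupby("animal").size()
        assert (counts == 2).all()
        assert set(ds.table.df["treatment"]) == {"vehicle", "purmorphamine"}

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_explant_study(control_rate=0.01, genotype_drop_pp=5.0)


def test_truth_serializes_to_json(tmp_path):
    ds = simulate_length_study(seed=11)
    p = tmp_path / "truth.json"
    ds.truth.to_json(p)
    import json

    d = json.loads(p.read_text())
    assert d["family"] == "lognormal"
    assert "genotype[hom]" in d["effects"]
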