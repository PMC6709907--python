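import numpy as np
import pandas as pd
import pytest

from chondrofit import MeasurementTable, SamplerConfig, StudyDesign


@pytest.fixture
def fast_config():
    """Reduced sampler budget for simulation-heavy tests."""
    return SamplerConfig(chains=2, iterations=350, warmup=250, seed=0)


@pytest.fixture
def length_table():
    """Small continuous table: radius lengths, two genotypes, two litters."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(8):
        geno = "control" if i < 4 else "hom"
        rows.append(
            {
                "value": float(5000 * np.exp(rng.normal(-0.1 * (geno == "hom"), 0.05))),
                "genotype": geno,
                "litter": f"L{i % 2 + 1}",
                "animal": f"A{i+1}",
            }
        )
    return MeasurementTable(pd.DataFrame(rows), kind="continuous")


@pytest.fixture
def count_table():
    """Small count table: BrdU labelled/total per animal."""
    rng = np.random.default_rng(43)
    rows = []
    for i in range(8):
        geno = "control" if i < 4 else "hom"
        total = int(rng.integers(200, 601))
        p = 0.30 - 0.05 * (geno == "hom")
        rows.append(
            {
                "labelled": int(rng.binomial(total, p)),
                "total": total,
                "genotype": geno,
                "litter": f"L{i % 2 + 1}",
                "animal": f"A{i+1}",
                "region": "columnar",
            }
        )
    return MeasurementTable(pd.DataFrame(rows), kind="count")


@pytest.fixture
def lognormal_design():
    return StudyDesign(family="lognormal", effect_terms=["genotype"], group_intercept_factors=["litter"])


@pytest.fixture
def binomial_design():
    return StudyDesign(family="binomial_logit", effect_terms=["genotype"], group_intercept_factors=["litter"])


def two_group_lognormal(seed: int, n0: int = 4, n1: int = 4, beta: float = 0.0, sigma: float = 0.1):
    """A minimal two-group continuous table without group structure beyond animal."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n0 + n1):
        mutant = i >= n0
        rows.append(
            {
                "value": float(np.exp(rng.normal(8.5 + beta * mutant, sigma))),
                "genotype": "hom" if mutant else "control",
                "animal": f"A{i+1}",
            }
        )
    return MeasurementTable(pd.DataFrame(rows), kind="continuous")


def two_group_binomial(seed: int, n0: int = 4, n1: int = 4, p0: float = 0.3, p1: float = 0.25):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n0 + n1):
        mutant = i >= n0
        total = int(rng.integers(150, 400))
        rows.append(
            {
                "labelled": int(rng.binomial(total, p1 if mutant else p0)),
                "total": total,
                "genotype": "hom" if mutant else "control",
                "animal": f"A{i+1}",
            }
        )
    return MeasurementTable(pd.DataFrame(rows), kind="count")
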