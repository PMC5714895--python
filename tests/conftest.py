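"""Shared fixtures: small crafted designs and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from modnet.expression_io import MUTANT, NON_MUTANT, ExpressionMatrix, SampleDesign
from modnet.simulate import SimulationConfig, simulate_dataset


def make_design(
    pairs=(("3mlpa", "3MWT"), ("1mlpa", "1MWT")),
    stages=("S1", "S2", "S3", "S4", "S5"),
    n_reps=3,
) -> SampleDesign:
    rows = []
    for mut, wt in pairs:
        for geno, klass, partner in ((mut, MUTANT, wt), (wt, NON_MUTANT, mut)):
            for s in stages:
                for r in range(1, n_reps + 1):
                    rows.append(
                        {
                            "sample_id": f"{geno}_{s}_r{r}",
                            "genotype": geno,
                            "stage": s,
                            "replicate": r,
                            "genotype_class": klass,
                            "mutant_partner": partner,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows), stages=stages)


@pytest.fixture
def standard_design() -> SampleDesign:
    """4 genotypes (2 mutant pairs) x 5 stages x 3 replicates."""
    return make_design()


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default synthetic dataset, shared read-only across tests."""
    return simulate_dataset(SimulationConfig(seed=1234))


@pytest.fixture
def counts_3x2() -> ExpressionMatrix:
    df = pd.DataFrame(
        {"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=["gA", "gB", "gC"]
    )
    return ExpressionMatrix(df, scale="raw_counts")
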