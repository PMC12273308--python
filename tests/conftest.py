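import numpy as np
import pandas as pd
import pytest

from rumenpred import preset, simulate_population
from rumenpred.data_io import PhenoTable


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by integration-style unit tests."""
    cfg = preset(
        "custom",
        h2=0.3,
        m2=0.4,
        n=120,
        n_snps=200,
        n_tags=240,
        n_heritable=120,
        n_factors=3,
        seed=7,
    )
    return simulate_population(cfg)


@pytest.fixture()
def toy_pheno():
    """Ten animals, two cohorts, years 2014-2016 (6 early, 4 late)."""
    table = pd.DataFrame(
        {
            "trait": np.arange(10, dtype=float),
            "year": [2014, 2014, 2014, 2015, 2015, 2015, 2016, 2016, 2016, 2016],
            "cohort": ["A"] * 5 + ["B"] * 5,
            "group": ["g1", "g2"] * 5,
            "cov": np.linspace(-1, 1, 10),
        },
        index=pd.Index([f"s{i}" for i in range(10)], name="sample_id"),
    )
    return PhenoTable(table, traits=["trait"], class_cols=["group"],
                      covariate_cols=["cov"], cohort_col="cohort", year_col="year")
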