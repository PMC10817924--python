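"""Shared fixtures: small seeded synthetic cohorts and metabolomes."""

import numpy as np
import pandas as pd
import pytest

from crcdiet import PlantedFactor, SimConfig, generate_cohort, generate_metabolome


@pytest.fixture(scope="session")
def two_factor_config() -> SimConfig:
    return SimConfig(
        n_pairs=400,
        n_foods=12,
        planted_factors=[
            PlantedFactor("A", [0, 1, 2, 3], [0.8, 0.75, 0.7, 0.6]),
            PlantedFactor("B", [6, 7, 8, 9], [0.8, 0.75, 0.7, 0.65]),
        ],
        apriori_defs={"comp_ab": [0, 6], "comp_a": [0, 1]},
        n_features=20,
        planted_feature_links=[(0, "A", 0.9), (1, "B", 0.6)],
        planted_log_or={"A": float(np.log(0.8))},
        seed=42,
    )


@pytest.fixture(scope="session")
def two_factor_cohort(two_factor_config):
    return generate_cohort(two_factor_config)


@pytest.fixture(scope="session")
def small_metabolome(two_factor_config, two_factor_cohort):
    cohort, diet, truth = two_factor_cohort
    return generate_metabolome(cohort, diet, two_factor_config, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def toy_matrix(values, qc_rows=0, seed=0):
    """Build a MetaboliteMatrix from a plain array; last `qc_rows` rows are
    sQC injections."""
    from crcdiet.metabolites import SQC, STUDY, MetaboliteMatrix

    values = np.asarray(values, dtype=float)
    n, m = values.shape
    rng = np.random.default_rng(seed)
    ids = [f"S{i:03d}" for i in range(n)]
    feats = [f"RP_{j + 1:04d}" for j in range(m)]
    roles = [STUDY] * (n - qc_rows) + [SQC] * qc_rows
    return MetaboliteMatrix(
        pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=feats),
        pd.DataFrame({"role": roles}, index=pd.Index(ids, name="sample_id")),
        pd.DataFrame(
            {
                "mode": ["RP"] * m,
                "rt_s": rng.uniform(30, 600, m),
                "mz": rng.uniform(70, 900, m),
            },
            index=pd.Index(feats, name="feature_id"),
        ),
    )
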