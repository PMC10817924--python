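"""Canonical synthetic study conditions.

Each function freezes one evaluation scenario — sample sizes, planted
effect sizes, noise levels — used across the test suite and the
acceptance script. The values are the study conditions themselves, chosen
once to reflect the matched case-control design the package models, not
tuning knobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import PlantedFactor, SimConfig, generate_cohort, generate_metabolome


def coverage_config(seed: int, n_pairs: int = 2000) -> SimConfig:
    """Cohort with one planted dietary factor carrying a protective per-SD
    log-odds of ln(0.89) — the coverage-calibration condition."""
    return SimConfig(
        n_pairs=n_pairs,
        n_foods=8,
        planted_factors=[PlantedFactor("A", [0, 1, 2, 3], [0.8, 0.7, 0.7, 0.6])],
        planted_log_or={"A": float(np.log(0.89))},
        seed=seed,
    )


def four_factor_config(seed: int, n_pairs: int = 1500) -> SimConfig:
    """24 foods, four well-separated planted factors of five foods each —
    the pattern-recovery condition."""
    blocks = [(0, "f1"), (6, "f2"), (12, "f3"), (18, "f4")]
    return SimConfig(
        n_pairs=n_pairs,
        n_foods=24,
        planted_factors=[
            PlantedFactor(name, list(range(s, s + 5)), [0.85, 0.8, 0.75, 0.7, 0.65])
            for s, name in blocks
        ],
        seed=seed,
    )


def frequency_matrix(diet: pd.DataFrame) -> pd.DataFrame:
    """Extract the ordinal frequency block (participants x foods)."""
    cols = [c for c in diet.columns if c.startswith("freq_")]
    return diet[cols].rename(columns=lambda c: c[5:])


def noise_diet(seed: int, n: int = 600, p: int = 24) -> pd.DataFrame:
    """Structure-free ordinal diet matrix (independent uniform levels)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.integers(1, 10, size=(n, p)),
        columns=[f"food_{i + 1:02d}" for i in range(p)],
        index=[f"P{i + 1:05d}" for i in range(n)],
    )


#: Planted monotone effects (log-intensity per SD of exposure) of the five
#: informative features in the rdCV signal condition.
SIGNAL_EFFECTS = (1.0, 0.8, 0.8, 0.6, 0.6)


def rdcv_signal_data(
    seed: int, n_pairs: int = 300, n_features: int = 200
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Metabolome of 2*n_pairs samples and n_features features, five of
    which carry monotone links to one dietary exposure; returns (features,
    response, planted feature ids)."""
    config = SimConfig(
        n_pairs=n_pairs,
        n_foods=8,
        planted_factors=[PlantedFactor("A", [0, 1, 2, 3], [0.8, 0.7, 0.7, 0.6])],
        n_features=n_features,
        planted_feature_links=[
            (j, "A", eff) for j, eff in enumerate(SIGNAL_EFFECTS)
        ],
        seed=seed,
    )
    cohort, diet, truth = generate_cohort(config)
    metab = generate_metabolome(cohort, diet, config, truth)
    X = metab.study
    y = truth.latent_scores["A"].reindex(X.index).rename("A")
    planted = list(X.columns[: len(SIGNAL_EFFECTS)])
    return X, y, planted


def rdcv_null_data(seed: int, n: int = 60, p: int = 12) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and a response independent of every feature."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"f{j + 1:02d}" for j in range(p)]
    )
    y = pd.Series(rng.standard_normal(n), index=X.index, name="y")
    return X, y


def confounded_triple(
    seed: int, n: int = 1000, noise: float = 0.3
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Feature and exposure both driven by one covariate: marginally highly
    rank-correlated, conditionally independent."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    feature = pd.Series(z + noise * rng.standard_normal(n), name="feature")
    exposure = pd.Series(z + noise * rng.standard_normal(n), name="exposure")
    return feature, exposure, pd.DataFrame({"z": z})
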