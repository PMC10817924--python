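"""Seeded synthetic matched case-control cohorts with planted structure.

The generator emulates the data structures of a nested 1:1 matched
case-control study of diet and colorectal cancer:

* matched pairs sharing sex, sub-cohort and age (the matching factors);
* an FFQ block of per-food intake levels on the 9-level ordinal scale,
  driven by planted latent dietary factors (so factor analysis has a known
  truth to recover), plus per-food amounts, total energy, alcohol intake
  and lifestyle covariates;
* an LC-MS-like feature matrix with planted monotone feature-exposure
  links, repeated pooled-QC injections and MCAR missingness;
* case status drawn from the exact conditional-logistic pair model with
  planted per-SD log-odds on standardised exposures, optionally
  site-specific.

Every planted quantity is recorded in :class:`GroundTruth` so downstream
stages can be checked against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .metabolites import SQC, STUDY, MetaboliteMatrix

SITES = ("proximal", "distal", "rectum")
#: Pair-level tumour-site probabilities (proximal, distal, rectum, unknown);
#: roughly the site mix of Scandinavian colorectal-cancer registries.
SITE_PROBS = (0.30, 0.30, 0.395, 0.005)

#: Cumulative probabilities cutting the standardised food propensity into
#: the 9 ordinal levels; fixed so that the discretisation is identical for
#: every seed and the latent factor structure stays recoverable.
LEVEL_CUTS = norm.ppf([0.10, 0.30, 0.45, 0.60, 0.75, 0.86, 0.94, 0.985])


@dataclass
class PlantedFactor:
    """A latent dietary factor loading on a subset of foods."""

    name: str
    foods: list[int]
    loadings: list[float]

    def __post_init__(self):
        if len(self.foods) != len(self.loadings):
            raise ValueError(f"factor {self.name!r}: foods and loadings differ in length")
        if not all(np.isfinite(self.loadings)):
            raise ValueError(f"factor {self.name!r}: loadings must be finite")
        if any(not (0.0 <= abs(l) <= 1.0) for l in self.loadings):
            raise ValueError(f"factor {self.name!r}: |loadings| must lie in [0, 1]")


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort. `seed` is mandatory."""

    n_pairs: int
    n_foods: int
    planted_factors: list[PlantedFactor]
    seed: int | None = None
    apriori_defs: dict[str, list[int]] = field(default_factory=dict)
    n_features: int = 0
    planted_feature_links: list[tuple[int, str, float]] = field(default_factory=list)
    planted_log_or: dict[str, float] = field(default_factory=dict)
    site_log_or: dict[str, dict[str, float]] = field(default_factory=dict)
    qc_every: int = 10
    qc_noise_cv: float = 0.10
    feature_noise_sd: float = 0.3
    missing_rate: float = 0.0
    food_noise_sd: float = 0.6
    covariate_missing_rate: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimConfig requires an explicit seed (reproducibility)")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.n_foods < 1:
            raise ValueError("n_foods must be >= 1")
        if not self.planted_factors:
            raise ValueError("at least one planted factor is required")
        self.planted_factors = [
            f if isinstance(f, PlantedFactor) else PlantedFactor(*f)
            for f in self.planted_factors
        ]
        names = [f.name for f in self.planted_factors]
        if len(set(names)) != len(names):
            raise ValueError("planted factor names must be unique")
        for f in self.planted_factors:
            if any(i < 0 or i >= self.n_foods for i in f.foods):
                raise ValueError(f"factor {f.name!r} references foods outside 0..{self.n_foods - 1}")
        for comp, idx in self.apriori_defs.items():
            if any(i < 0 or i >= self.n_foods for i in idx):
                raise ValueError(f"a priori component {comp!r} references unknown foods")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        exposures = self.exposure_names()
        for exp in self.planted_log_or:
            if exp not in exposures:
                raise ValueError(f"planted log-OR references unknown exposure {exp!r}")
        for exp in self.site_log_or:
            if exp not in exposures:
                raise ValueError(f"site log-OR references unknown exposure {exp!r}")
        for j, exp, _ in self.planted_feature_links:
            if not (0 <= j < self.n_features):
                raise ValueError(f"feature link references feature {j} outside 0..{self.n_features - 1}")
            if exp not in exposures:
                raise ValueError(f"feature link references unknown exposure {exp!r}")

    def exposure_names(self) -> set[str]:
        return (
            {f.name for f in self.planted_factors}
            | set(self.apriori_defs)
            | {"alcohol", "energy"}
        )

    def food_names(self) -> list[str]:
        return [f"food_{i + 1:02d}" for i in range(self.n_foods)]


@dataclass
class GroundTruth:
    """Planted quantities, retrievable unchanged for any seed."""

    factor_loadings: pd.DataFrame  # foods x factors
    latent_scores: pd.DataFrame  # participants x factors
    log_odds: dict[str, float]
    site_log_odds: dict[str, dict[str, float]]
    feature_links: pd.DataFrame  # feature_id, exposure, effect
    exposures: pd.DataFrame  # standardised exposure values used in the outcome model

    def to_json(self, path) -> None:
        payload = {
            "factor_loadings": self.factor_loadings.to_dict(),
            "log_odds": self.log_odds,
            "site_log_odds": self.site_log_odds,
            "feature_links": self.feature_links.to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _exposure_value(
    name: str,
    config: SimConfig,
    latent: pd.DataFrame,
    amounts: pd.DataFrame,
    cohort: pd.DataFrame,
) -> np.ndarray:
    """Raw (unstandardised) values of a named exposure per participant."""
    if name in latent.columns:
        return latent[name].to_numpy()
    if name in config.apriori_defs:
        cols = [amounts.columns[i] for i in config.apriori_defs[name]]
        return amounts[cols].sum(axis=1).to_numpy()
    if name == "alcohol":
        return cohort["alcohol_g"].to_numpy()
    if name == "energy":
        return cohort["energy_kcal"].to_numpy()
    raise KeyError(f"unknown exposure {name!r}")


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("exposure has zero variance; cannot standardise")
    return (x - x.mean()) / sd


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one matched cohort: (cohort table, diet matrix, ground truth).

    The cohort table has one row per participant (2 * n_pairs rows) with
    pair id, case status, matching factors (sex, sub-cohort, age — exactly
    equal within pair), lifestyle covariates, energy and alcohol intake,
    and the case's tumour site. The diet matrix carries per-food ordinal
    frequency levels (``freq_*``, 1-9), per-food amounts in g/day
    (``amt_*``), total energy and precomputed calcium/fiber totals.
    """
    rng = np.random.default_rng(config.seed)
    n_pairs, n_foods = config.n_pairs, config.n_foods
    n = 2 * n_pairs
    ids = [f"P{i + 1:05d}" for i in range(n)]
    pair_ids = np.repeat([f"pair_{i + 1:05d}" for i in range(n_pairs)], 2)

    # pair-level matching factors
    sex = np.repeat(rng.choice(["F", "M"], size=n_pairs, p=[0.494, 0.506]), 2)
    subcohort = np.repeat(
        rng.choice(["VIP", "MONICA"], size=n_pairs, p=[0.913, 0.087]), 2
    )
    age = np.repeat(rng.choice([40.0, 50.0, 60.0], size=n_pairs, p=[0.15, 0.35, 0.5]), 2)

    # lifestyle covariates (individual level)
    bmi = np.clip(rng.normal(26.4, 4.0, size=n), 16.0, 45.0)
    smoking = rng.choice(["never", "ex", "current"], size=n, p=[0.43, 0.35, 0.22])
    activity = rng.choice(["none", "low", "medium", "high"], size=n, p=[0.43, 0.26, 0.26, 0.05])
    education = rng.choice(["elementary", "secondary", "post-secondary"], size=n, p=[0.38, 0.44, 0.18])
    energy = np.clip(rng.normal(1700.0, 600.0, size=n), 800.0, None)
    drinks = rng.random(n) > 0.09
    alcohol = np.where(
        drinks,
        np.exp(rng.normal(np.where(sex == "M", 1.4, 0.9), 0.8)),
        0.0,
    )

    # latent dietary factors -> ordinal food frequencies
    factor_names = [f.name for f in config.planted_factors]
    z = rng.standard_normal((n, len(factor_names)))
    latent = pd.DataFrame(z, index=ids, columns=factor_names)
    Lam = np.zeros((n_foods, len(factor_names)))
    for j, f in enumerate(config.planted_factors):
        Lam[np.asarray(f.foods, dtype=int), j] = f.loadings
    propensity = z @ Lam.T + config.food_noise_sd * rng.standard_normal((n, n_foods))
    scale = np.sqrt((Lam**2).sum(axis=1) + config.food_noise_sd**2)
    propensity /= scale
    levels = np.searchsorted(LEVEL_CUTS, propensity) + 1  # 1..9

    foods = config.food_names()
    # deterministic per-food portion sizes (g per eating occasion)
    portions = 20.0 + 15.0 * ((np.arange(n_foods) * 7) % 11)
    freq_map = np.array([0.0, 0.5 / 30, 2.0 / 30, 1 / 7, 2.5 / 7, 5 / 7, 1.0, 2.5, 4.0])
    freq_day = freq_map[levels - 1]
    amounts = freq_day * portions

    diet = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    for i, food in enumerate(foods):
        diet[f"freq_{food}"] = levels[:, i]
    for i, food in enumerate(foods):
        diet[f"amt_{food}"] = amounts[:, i]
    diet["energy_kcal"] = energy
    # precomputed nutrient totals (food-composition lookups are out of scope)
    w = 0.8 + 0.4 * np.cos(np.arange(n_foods))
    diet["calcium_mg"] = amounts @ (3.0 * np.abs(w)) + np.exp(rng.normal(4.0, 0.3, size=n))
    diet["fiber_g"] = amounts @ (0.05 * np.abs(np.roll(w, 3))) + np.exp(rng.normal(0.5, 0.3, size=n))

    cohort = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "case": 0,
            "sex": sex,
            "cohort": subcohort,
            "age": age,
            "bmi": bmi,
            "smoking": smoking,
            "activity": activity,
            "education": education,
            "energy_kcal": energy,
            "alcohol_g": alcohol,
            "tumor_site": "",
        },
        index=pd.Index(ids, name="participant_id"),
    )

    # optional MCAR missingness in adjustment covariates
    if config.covariate_missing_rate > 0:
        for col in ("bmi", "smoking", "activity", "education"):
            mask = rng.random(n) < config.covariate_missing_rate
            cohort.loc[mask, col] = np.nan

    # standardised exposures entering the outcome model
    amount_cols = diet[[f"amt_{f}" for f in foods]]
    amount_cols = amount_cols.rename(columns=lambda c: c[4:])
    used = sorted(set(config.planted_log_or) | set(config.site_log_or))
    recorded = list(dict.fromkeys(used + [f.name for f in config.planted_factors]))
    exposures = pd.DataFrame(index=cohort.index)
    for name in recorded:
        exposures[name] = _standardise(
            _exposure_value(name, config, latent, amount_cols, cohort)
        )

    # pair-level tumour site, then case status from the conditional model
    site_labels = list(SITES) + ["unknown"]
    pair_site = rng.choice(site_labels, size=n_pairs, p=SITE_PROBS)
    eta = np.zeros(n)
    for name in used:
        beta = config.planted_log_or.get(name, 0.0)
        x = exposures[name].to_numpy()
        eta += beta * x
        extra = config.site_log_or.get(name)
        if extra:
            site_beta = np.array([extra.get(s, 0.0) for s in pair_site])
            eta += np.repeat(site_beta, 2) * x
    eta1, eta2 = eta[0::2], eta[1::2]
    p_first = 1.0 / (1.0 + np.exp(-(eta1 - eta2)))
    first_is_case = rng.random(n_pairs) < p_first
    case = np.zeros(n, dtype=int)
    case[0::2] = first_is_case
    case[1::2] = ~first_is_case
    cohort["case"] = case
    cohort.loc[case == 1, "tumor_site"] = np.repeat(pair_site, 2)[case == 1]

    truth = GroundTruth(
        factor_loadings=pd.DataFrame(Lam, index=foods, columns=factor_names),
        latent_scores=latent,
        log_odds=dict(config.planted_log_or),
        site_log_odds={k: dict(v) for k, v in config.site_log_or.items()},
        feature_links=pd.DataFrame(
            config.planted_feature_links, columns=["feature", "exposure", "effect"]
        ),
        exposures=exposures,
    )
    return cohort, diet, truth


def generate_metabolome(
    cohort: pd.DataFrame,
    diet: pd.DataFrame,
    config: SimConfig,
    truth: GroundTruth | None = None,
) -> MetaboliteMatrix:
    """Generate the feature matrix for a cohort produced by generate_cohort.

    Features with planted links are monotone in their exposure (the effect
    enters on the log-intensity scale); all other features are pure noise.
    Pooled-QC injections replicate the mean study profile with technical
    noise of coefficient of variation `qc_noise_cv`, inserted every
    `qc_every` study samples. Missing study cells are MCAR at
    `missing_rate`.
    """
    if not cohort.index.equals(diet.index):
        raise ValueError("cohort and diet must share participant ids")
    if config.missing_rate >= 1.0:
        raise ValueError("missing_rate must be < 1")
    if config.n_features < 1:
        raise ValueError("config.n_features must be >= 1 to generate a metabolome")
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    n = len(cohort)
    m = config.n_features

    factor_names = [f.name for f in config.planted_factors]
    if truth is not None:
        latent = truth.latent_scores
    else:
        latent = pd.DataFrame(np.empty((n, 0)), index=cohort.index)
        needed = {e for _, e, _ in config.planted_feature_links if e in factor_names}
        if needed:
            raise ValueError(
                f"feature links reference latent factors {sorted(needed)}; "
                "pass the GroundTruth from generate_cohort"
            )
    foods = config.food_names()
    amount_cols = diet[[f"amt_{f}" for f in foods]].rename(columns=lambda c: c[4:])

    mu = rng.normal(11.5, 0.5, size=m)  # baseline log-intensities
    log_int = mu + config.feature_noise_sd * rng.standard_normal((n, m))
    for j, exp_name, effect in config.planted_feature_links:
        x = _standardise(_exposure_value(exp_name, config, latent, amount_cols, cohort))
        log_int[:, j] += effect * x
    intens = np.exp(log_int)

    modes = np.where(np.arange(m) % 2 == 0, "RP", "RN")
    feature_ids = [f"{modes[j]}_{j + 1:04d}" for j in range(m)]
    feature_meta = pd.DataFrame(
        {
            "mode": modes,
            "rt_s": rng.uniform(30.0, 600.0, size=m).round(2),
            "mz": rng.uniform(70.0, 900.0, size=m).round(4),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    pooled = intens.mean(axis=0)
    n_qc = max(2, n // max(config.qc_every, 1))
    qc = pooled * (1.0 + config.qc_noise_cv * rng.standard_normal((n_qc, m)))
    qc = np.clip(qc, 1e-9, None)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        intens = np.where(mask, np.nan, intens)

    qc_ids = [f"sQC_{i + 1:03d}" for i in range(n_qc)]
    all_ids = list(cohort.index) + qc_ids
    intensities = pd.DataFrame(
        np.vstack([intens, qc]),
        index=pd.Index(all_ids, name="sample_id"),
        columns=feature_meta.index,
    )
    sample_meta = pd.DataFrame(
        {"role": [STUDY] * n + [SQC] * n_qc},
        index=intensities.index,
    )
    return MetaboliteMatrix(intensities, sample_meta, feature_meta)
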