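"""End-to-end pipeline driver: simulate -> prepare diet -> derive patterns
-> risk models -> metabolite prep -> diet-metabolome models -> triplot.

This is the glue the numbered analysis scripts (and the determinism check)
run; every computational step lives in the stage modules. All outputs are
UTF-8 TSV/JSON with a fixed float format, so a repeated run from the same
seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diet as dietmod
from .dietmetab import (
    RdcvSettings,
    partial_spearman,
    permutation_test,
    rdcv_rf,
    select_diet_features,
)
from .metabolites import cv_filter, rf_impute
from .patterns import stability_select
from .risk import add_alcohol_category, fit_clogit, risk_table, stratified_analysis
from .simulate import PlantedFactor, SimConfig, generate_cohort, generate_metabolome
from .triplot import component_associations, export_triplot, pca_selected

_FLOAT_FMT = "%.12g"


def default_sim_config(
    seed: int,
    n_pairs: int = 400,
    n_features: int = 40,
    missing_rate: float = 0.03,
) -> SimConfig:
    """A standard desk-scale scenario: 16 foods, three planted dietary
    factors, two a priori components, planted metabolite links for the
    alcohol-like factor and the fruit/vegetable component, and a modest
    protective per-SD log-odds on the breakfast-like factor."""
    return SimConfig(
        n_pairs=n_pairs,
        n_foods=16,
        planted_factors=[
            PlantedFactor("breakfast", [0, 1, 2, 3], [0.8, 0.75, 0.7, 0.6]),
            PlantedFactor("meat", [5, 6, 7, 8], [0.8, 0.7, 0.7, 0.65]),
            PlantedFactor("alcohol_pattern", [10, 11, 12], [0.85, 0.8, 0.7]),
        ],
        apriori_defs={"fruit_veg": [3, 4, 13], "red_meat": [5, 6, 7]},
        n_features=n_features,
        planted_feature_links=[
            (0, "alcohol", 0.9),
            (1, "alcohol", 0.7),
            (2, "fruit_veg", 0.8),
            (3, "fruit_veg", 0.6),
        ],
        planted_log_or={"breakfast": float(np.log(0.89))},
        missing_rate=missing_rate,
        seed=seed,
    )


@dataclass
class PipelineSettings:
    """Scale knobs for one pipeline run (desk-scale defaults)."""

    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_rep: int = 5
    rdcv: RdcvSettings = field(
        default_factory=lambda: RdcvSettings(
            n_rep=1, n_outer=4, n_inner=3, var_ratio=0.45, n_trees=50, min_samples=40
        )
    )
    n_perm: int = 20
    q2_thresh: float = 0.15
    n_components: int = 3
    rdcv_exposures: tuple[str, ...] = ("alcohol", "fruit_veg")


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kwargs)


def run_pipeline(
    seed: int,
    outdir,
    sim_config: SimConfig | None = None,
    settings: PipelineSettings | None = None,
) -> dict:
    """Run every stage on one synthetic cohort and write all tables under
    `outdir`. Returns a summary dict (also written as summary.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = settings or PipelineSettings()
    config = sim_config or default_sim_config(seed)

    # 1. simulate
    cohort, diet, truth = generate_cohort(config)
    metab = generate_metabolome(cohort, diet, config, truth)
    _write(cohort, outdir / "cohort.tsv")
    _write(diet, outdir / "diet.tsv")
    truth.to_json(outdir / "ground_truth.json")
    _write(metab.intensities, outdir / "features_raw.tsv")
    _write(metab.sample_meta, outdir / "samples.tsv")

    # 2. diet preparation
    cohort = add_alcohol_category(cohort)
    foods = config.food_names()
    freq_levels = diet[[f"freq_{f}" for f in foods]].rename(columns=lambda c: c[5:])
    amounts = diet[[f"amt_{f}" for f in foods]].rename(columns=lambda c: c[4:])
    defs = {
        name: [foods[i] for i in idx] for name, idx in config.apriori_defs.items()
    }
    components = dietmod.build_apriori_components(amounts, defs)
    components_adj = dietmod.energy_adjust(components, diet["energy_kcal"])
    _write(components_adj, outdir / "apriori_components.tsv")

    # 3. data-driven patterns
    pattern_set = stability_select(
        freq_levels,
        k_range=settings.k_range,
        n_rep=settings.n_rep,
        seed=seed + 10,
    )
    if pattern_set.scores is not None:
        scores_adj = dietmod.energy_adjust(pattern_set.scores, diet["energy_kcal"])
        _write(scores_adj, outdir / "pattern_scores.tsv")
        loadings = pd.concat({p.name: p.loadings for p in pattern_set.patterns}, axis=1)
        _write(loadings, outdir / "pattern_loadings.tsv")
    else:
        scores_adj = pd.DataFrame(index=cohort.index)
    _write(pattern_set.fitness_table, outdir / "pattern_fitness.tsv", index=False)

    # exposures entering risk and diet-metabolome models
    exposures = pd.concat([scores_adj, components_adj], axis=1)
    exposures["alcohol"] = dietmod.energy_adjust(
        cohort["alcohol_g"], diet["energy_kcal"]
    )
    _write(exposures, outdir / "exposures.tsv")

    # 4. risk models
    estimates = []
    for col in exposures.columns:
        estimates.append(fit_clogit(cohort, exposures[col], exposure_name=col))
        for strat in (("sex",), ("site",)):
            try:
                estimates.extend(
                    stratified_analysis(
                        cohort, exposures[col], strata=strat, exposure_name=col
                    )
                )
            except ValueError:
                # a sparse stratum can be inestimable at desk scale
                continue
    _write(risk_table(estimates), outdir / "risk.tsv", index=False)

    # 5. metabolite preparation
    filtered, cv_report = cv_filter(metab, threshold=0.30)
    _write(cv_report, outdir / "cv_report.tsv")
    complete = rf_impute(filtered, seed=seed + 20, n_trees=50)
    _write(complete.intensities, outdir / "features_clean.tsv")

    # 6. diet-metabolome rdCV models
    study = complete.study
    models = []
    for name in settings.rdcv_exposures:
        if name not in exposures.columns:
            continue
        model = rdcv_rf(
            study,
            exposures[name].reindex(study.index),
            settings.rdcv,
            seed=seed + 30,
            exposure_name=name,
        )
        if model.q2 > settings.q2_thresh and settings.n_perm >= 20:
            model = permutation_test(
                study,
                exposures[name].reindex(study.index),
                settings.rdcv,
                n_perm=settings.n_perm,
                seed=seed + 40,
                observed=model,
            )
        models.append(model)
    associations = []
    for m in models:
        for feat in m.selected_features:
            associations.append(
                partial_spearman(
                    study[feat],
                    exposures[m.exposure].reindex(study.index),
                    cohort=cohort.loc[study.index],
                    feature_name=feat,
                    exposure_name=m.exposure,
                )
            )
    selected = select_diet_features(models, associations, q2_thresh=settings.q2_thresh)
    _write(selected, outdir / "selected_features.tsv")
    model_report = pd.DataFrame(
        {
            "exposure": [m.exposure for m in models],
            "q2": [m.q2 for m in models],
            "perm_p": [m.permutation_p for m in models],
            "perm_p_parametric": [m.permutation_p_parametric for m in models],
            "n_selected": [len(m.selected_features) for m in models],
        }
    )
    _write(model_report, outdir / "rdcv_models.tsv", index=False)

    # 7. triplot integration
    summary: dict = {
        "seed": seed,
        "n_pairs": config.n_pairs,
        "n_patterns": len(pattern_set.patterns),
        "n_features_raw": metab.intensities.shape[1],
        "n_features_clean": complete.intensities.shape[1],
        "n_selected": int(len(selected)),
        "rdcv_q2": {m.exposure: m.q2 for m in models},
    }
    if len(selected) >= 2:
        # log-intensities: LC-MS features are log-normal, and linear PCA on
        # the raw scale is dominated by a handful of extreme values
        sel_matrix = np.log(study[selected.index.tolist()])
        pca = pca_selected(sel_matrix)
        tri = component_associations(
            pca,
            cohort.loc[study.index],
            exposures.reindex(study.index),
            n_components=min(settings.n_components, pca.scores.shape[1]),
        )
        export_triplot(tri, outdir)
        summary["triplot_components"] = int(tri.loadings.shape[1])
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
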