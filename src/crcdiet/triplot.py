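"""Triplot integration: PCA of diet-selected metabolite features, risk
estimates for the component scores, and covariate-adjusted component-
exposure correlations, emitted as plot-ready tables.

A principal component analysis on the autoscaled selected-feature matrix
summarises the diet-reflecting metabolome; each component score is then
(i) entered as the exposure of the matched-pair conditional logistic model
(overall and stratified) and (ii) correlated with every dietary exposure
by covariate-adjusted partial Spearman correlation. The three result
tables — loadings, exposure correlations and odds ratios — drive a single
overlay display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dietmetab import partial_spearman
from .risk import RiskEstimate, fit_clogit, risk_table, stratified_analysis


@dataclass
class TriplotResult:
    loadings: pd.DataFrame  # features x components, orthonormal columns
    scores: pd.DataFrame  # participants x components, uncorrelated
    explained_variance: pd.Series  # proportion per component, non-increasing
    risk: list[RiskEstimate] = field(default_factory=list)
    correlations: pd.DataFrame | None = None  # component x exposure rho (+p)


def pca_selected(features: pd.DataFrame) -> TriplotResult:
    """PCA of the selected-feature matrix after autoscaling.

    Features are centred and scaled to unit variance, then decomposed by
    SVD. Loadings columns are orthonormal; each component's sign is fixed
    so its largest-|loading| entry is positive, making results platform-
    reproducible. Raises on missing values or constant features.
    """
    X = features.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a participants x features matrix with >= 2 features")
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix; impute first")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = list(features.columns[sd == 0])
        raise ValueError(f"constant features cannot be autoscaled: {dead}")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    n_comp = Vt.shape[0]
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    loadings = pd.DataFrame(Vt.T, index=features.columns, columns=comp_names)
    scores = pd.DataFrame(U * s, index=features.index, columns=comp_names)
    ev = s**2 / np.sum(s**2)
    return TriplotResult(
        loadings=loadings,
        scores=scores,
        explained_variance=pd.Series(ev, index=comp_names, name="explained_variance"),
    )


def component_associations(
    pca: TriplotResult,
    cohort: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: list[str] | None = None,
    n_components: int = 3,
    strata: tuple[tuple[str, ...], ...] = (("sex",), ("site",)),
) -> TriplotResult:
    """Associate the first `n_components` PCA scores with CRC risk and
    with every dietary exposure.

    Risk: conditional logistic regression per component (overall plus the
    requested stratifications). Exposure reflection: covariate-adjusted
    partial Spearman correlation of the component score with each column
    of `exposures`. Returns a TriplotResult carrying both.
    """
    comp_names = list(pca.scores.columns[:n_components])
    risk: list[RiskEstimate] = []
    corr_rows = []
    for comp in comp_names:
        score = pca.scores[comp].reindex(cohort.index)
        risk.append(
            fit_clogit(cohort, score, covariates=covariates, exposure_name=comp)
        )
        for strat in strata:
            try:
                risk.extend(
                    stratified_analysis(
                        cohort, score, covariates=covariates, strata=strat,
                        exposure_name=comp,
                    )
                )
            except ValueError:
                continue  # a sparse stratum can be inestimable at desk scale
        for exp_name in exposures.columns:
            rec = partial_spearman(
                score,
                exposures[exp_name].reindex(cohort.index),
                cohort=cohort,
                feature_name=comp,
                exposure_name=exp_name,
            )
            corr_rows.append(
                {"component": comp, "exposure": exp_name, "rho": rec.rho, "p": rec.p, "n": rec.n}
            )
    return TriplotResult(
        loadings=pca.loadings[comp_names],
        scores=pca.scores[comp_names],
        explained_variance=pca.explained_variance[comp_names],
        risk=risk,
        correlations=pd.DataFrame(corr_rows),
    )


_FLOAT_FMT = "%.12g"


def export_triplot(result: TriplotResult, outdir) -> dict[str, Path]:
    """Write plot-ready TSVs: loadings, component scores, explained
    variance, exposure correlations and odds ratios (with SEs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["loadings"] = outdir / "triplot_loadings.tsv"
    result.loadings.to_csv(paths["loadings"], sep="\t", float_format=_FLOAT_FMT)
    paths["scores"] = outdir / "triplot_scores.tsv"
    result.scores.to_csv(paths["scores"], sep="\t", float_format=_FLOAT_FMT)
    paths["explained"] = outdir / "triplot_explained_variance.tsv"
    result.explained_variance.to_frame().to_csv(
        paths["explained"], sep="\t", float_format=_FLOAT_FMT
    )
    if result.correlations is not None:
        paths["correlations"] = outdir / "triplot_correlations.tsv"
        result.correlations.to_csv(
            paths["correlations"], sep="\t", index=False, float_format=_FLOAT_FMT
        )
    if result.risk:
        paths["ors"] = outdir / "triplot_ors.tsv"
        tab = risk_table(result.risk)
        tab["se"] = [e.se for e in result.risk]
        tab["beta"] = [e.beta for e in result.risk]
        tab.to_csv(paths["ors"], sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(outdir / "triplot_meta.json", "w", encoding="utf-8") as fh:
        json.dump({"n_components": int(result.loadings.shape[1])}, fh)
    return paths


def load_triplot(outdir) -> TriplotResult:
    """Reload an exported triplot directory into a TriplotResult."""
    outdir = Path(outdir)
    loadings = pd.read_csv(outdir / "triplot_loadings.tsv", sep="\t", index_col=0)
    scores = pd.read_csv(outdir / "triplot_scores.tsv", sep="\t", index_col=0)
    ev = pd.read_csv(outdir / "triplot_explained_variance.tsv", sep="\t", index_col=0)[
        "explained_variance"
    ]
    corr_path = outdir / "triplot_correlations.tsv"
    correlations = (
        pd.read_csv(corr_path, sep="\t") if corr_path.exists() else None
    )
    risk: list[RiskEstimate] = []
    ors_path = outdir / "triplot_ors.tsv"
    if ors_path.exists():
        tab = pd.read_csv(ors_path, sep="\t")
        for _, r in tab.iterrows():
            risk.append(
                RiskEstimate(
                    exposure=r["exposure"],
                    stratum=r["stratum"],
                    n_pairs=int(r["n_pairs"]),
                    or_=r["OR"],
                    ci_low=r["ci_low"],
                    ci_high=r["ci_high"],
                    p=r["p"],
                    beta=r["beta"],
                    se=r["se"],
                    stable=bool(r["stable"]),
                )
            )
    return TriplotResult(
        loadings=loadings,
        scores=scores,
        explained_variance=ev,
        risk=risk,
        correlations=correlations,
    )


def plot_triplot(result: TriplotResult, path, components=("PC1", "PC2")) -> None:
    """Static overlay figure: loading arrows, exposure-correlation rays and
    OR glyphs with SE whiskers, on two chosen components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cx, cy = components
    fig, ax = plt.subplots(figsize=(7, 7))
    for feat in result.loadings.index:
        x, y = result.loadings.loc[feat, cx], result.loadings.loc[feat, cy]
        ax.annotate(
            "", xy=(x, y), xytext=(0, 0), arrowprops={"arrowstyle": "->", "color": "k", "lw": 0.6}
        )
    if result.correlations is not None:
        for exp_name, grp in result.correlations.groupby("exposure"):
            grp = grp.set_index("component")
            if cx in grp.index and cy in grp.index:
                x, y = grp.loc[cx, "rho"], grp.loc[cy, "rho"]
                ax.plot([0, x], [0, y], color="tab:blue", lw=1.2)
                ax.text(x, y, exp_name, color="tab:blue", fontsize=8)
    overall = {e.exposure: e for e in result.risk if e.stratum == "all"}
    for j, (comp, e) in enumerate(overall.items()):
        if comp not in (cx, cy):
            continue
        x = 0.9 if comp == cx else 0.0
        y = 0.9 if comp == cy else 0.0
        ax.errorbar([x], [y], yerr=[e.se], fmt="o", color="tab:red", capsize=3)
        ax.text(x, y, f"{comp}: OR {e.or_:.2f}", color="tab:red", fontsize=8)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(cx)
    ax.set_ylabel(cy)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
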