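#!/usr/bin/env python
"""Integrate diet-selected metabolite features with exposures and risk.

PCA of the selected-feature matrix, conditional-logistic ORs for the
component scores (overall / by sex / by site), partial-Spearman
correlations of components with every exposure; writes the plot-ready
tables and a static triplot figure under results/triplot/.
"""

import argparse
from pathlib import Path

import pandas as pd

from crcdiet import (
    add_alcohol_category,
    component_associations,
    energy_adjust,
    export_triplot,
    pca_selected,
)
from crcdiet.triplot import plot_triplot


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--diet", type=Path, default=Path("results/diet"))
    ap.add_argument("--metab", type=Path, default=Path("results/metabolome"))
    ap.add_argument("--selected", type=Path,
                    default=Path("results/dietmetab/selected_features.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/triplot"))
    ap.add_argument("--components", type=int, default=3)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = add_alcohol_category(
        pd.read_csv(args.data / "cohort.tsv", sep="\t", index_col=0)
    )
    diet = pd.read_csv(args.data / "diet.tsv", sep="\t", index_col=0)
    features = pd.read_csv(args.metab / "features_clean.tsv", sep="\t", index_col=0)
    study = features.loc[features.index.intersection(cohort.index)]
    selected = pd.read_csv(args.selected, sep="\t", index_col=0)
    if len(selected) < 2:
        print(f"only {len(selected)} selected features; need >= 2 for PCA")
        return
    exposures = pd.read_csv(args.diet / "apriori_components.tsv", sep="\t", index_col=0)
    exposures["alcohol"] = energy_adjust(cohort["alcohol_g"], diet["energy_kcal"])

    # PCA on log intensities: LC-MS features are log-normal and the raw
    # scale would let a few extreme values dominate the components
    import numpy as np

    pca = pca_selected(np.log(study[selected.index.tolist()]))
    n_comp = min(args.components, pca.scores.shape[1])
    tri = component_associations(
        pca, cohort, exposures.reindex(study.index), n_components=n_comp
    )
    export_triplot(tri, args.out)
    if n_comp >= 2:
        plot_triplot(tri, args.out / "triplot.png")

    ev = tri.explained_variance
    print(f"PCA on {len(selected)} selected features; explained variance "
          + ", ".join(f"{c}={v:.1%}" for c, v in ev.items()))
    for e in tri.risk:
        if e.stratum == "all":
            print(f"  {e.exposure}: OR {e.or_:.2f} ({e.ci_low:.2f}-{e.ci_high:.2f}) "
                  f"p={e.p:.3f}")
    top = tri.correlations.reindex(
        tri.correlations["rho"].abs().sort_values(ascending=False).index
    ).head(4)
    for _, r in top.iterrows():
        print(f"  {r['component']} ~ {r['exposure']}: partial rho {r['rho']:.2f}")


if __name__ == "__main__":
    main()
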