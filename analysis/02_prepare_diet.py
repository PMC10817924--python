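#!/usr/bin/env python
"""Turn the raw FFQ block into analysis-ready exposures.

Reads results/data/, writes energy-adjusted a priori components, the
3-level alcohol covariate and per-day frequencies under results/diet/.
"""

import argparse
from pathlib import Path

import pandas as pd

from crcdiet import (
    build_apriori_components,
    categorize_alcohol,
    energy_adjust,
    map_frequency_levels,
)
from crcdiet.pipeline import _write, default_sim_config


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/diet"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = default_sim_config(args.seed)
    cohort = pd.read_csv(args.data / "cohort.tsv", sep="\t", index_col=0)
    diet = pd.read_csv(args.data / "diet.tsv", sep="\t", index_col=0)
    foods = config.food_names()

    freq_levels = diet[[f"freq_{f}" for f in foods]].rename(columns=lambda c: c[5:])
    freq_day = map_frequency_levels(freq_levels)
    _write(freq_day, args.out / "frequency_per_day.tsv")

    amounts = diet[[f"amt_{f}" for f in foods]].rename(columns=lambda c: c[4:])
    defs = {n: [foods[i] for i in idx] for n, idx in config.apriori_defs.items()}
    components = build_apriori_components(amounts, defs)
    components_adj = energy_adjust(components, diet["energy_kcal"])
    _write(components_adj, args.out / "apriori_components.tsv")

    alc = categorize_alcohol(cohort["alcohol_g"], cohort["sex"])
    _write(alc.rename("alcohol_cat").to_frame(), args.out / "alcohol_category.tsv")

    print(f"components (energy-adjusted, per 1000 kcal): {list(components.columns)}")
    print(alc.value_counts().to_string())


if __name__ == "__main__":
    main()
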