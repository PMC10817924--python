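#!/usr/bin/env python
"""Metabolite feature preparation: QC CV filter then RF imputation.

Reads the raw feature matrix, drops features with sQC CV > 30%, imputes
missing study intensities by iterative random forests, and writes the
clean matrix plus the CV report under results/metabolome/.
"""

import argparse
from pathlib import Path

import pandas as pd

from crcdiet import cv_filter, rf_impute
from crcdiet.metabolites import MetaboliteMatrix
from crcdiet.pipeline import _write


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20240)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/metabolome"))
    ap.add_argument("--cv", type=float, default=0.30)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    intensities = pd.read_csv(args.data / "features_raw.tsv", sep="\t", index_col=0)
    sample_meta = pd.read_csv(args.data / "samples.tsv", sep="\t", index_col=0)
    feature_meta = pd.read_csv(args.data / "feature_meta.tsv", sep="\t", index_col=0)
    mat = MetaboliteMatrix(intensities, sample_meta, feature_meta)

    filtered, report = cv_filter(mat, threshold=args.cv)
    _write(report, args.out / "cv_report.tsv")
    print(f"CV filter (<= {args.cv:.0%}): kept {filtered.intensities.shape[1]} "
          f"of {mat.intensities.shape[1]} features")

    n_missing = int(filtered.intensities.isna().sum().sum())
    complete = rf_impute(filtered, seed=args.seed + 20, n_trees=50)
    _write(complete.intensities, args.out / "features_clean.tsv")
    print(f"imputed {n_missing} missing cells; matrix is now complete")


if __name__ == "__main__":
    main()
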