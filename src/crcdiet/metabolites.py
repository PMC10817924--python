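"""LC-MS feature-matrix preparation: random-forest imputation and
QC-based coefficient-of-variation filtering.

The feature matrix holds untargeted metabolite intensities for study
samples plus repeated injections of a pooled study-specific quality
control sample (sQC). Technical reproducibility per feature is summarised
by the CV (sd/mean) over the sQC injections; features with CV above a
threshold (default 30%) are dropped. Missing intensities are imputed by an
iterative random-forest scheme before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

STUDY = "study"
SQC = "sqc"


@dataclass
class MetaboliteMatrix:
    """Samples x features intensity matrix with sample roles and feature
    metadata (ionisation mode, retention time, m/z)."""

    intensities: pd.DataFrame  # samples x features, NaN = missing
    sample_meta: pd.DataFrame  # index = sample id; column "role" in {study, sqc}
    feature_meta: pd.DataFrame  # index = feature id; mode, rt_s, mz
    cv: pd.Series | None = field(default=None)  # per-feature sQC CV, once computed

    def __post_init__(self):
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValueError("intensities and sample_meta must share sample ids")
        if not self.intensities.columns.equals(self.feature_meta.index):
            raise ValueError("intensities and feature_meta must share feature ids")
        if self.intensities.columns.has_duplicates:
            raise ValueError("feature ids must be unique")
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy() < 0).any():
                raise ValueError("intensities must be non-negative where present")

    @property
    def study(self) -> pd.DataFrame:
        """Intensities of study samples only."""
        return self.intensities.loc[self.sample_meta["role"] == STUDY]

    @property
    def sqc(self) -> pd.DataFrame:
        """Intensities of pooled-QC injections only."""
        return self.intensities.loc[self.sample_meta["role"] == SQC]

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.intensities.copy(),
            self.sample_meta.copy(),
            self.feature_meta.copy(),
            None if self.cv is None else self.cv.copy(),
        )


def qc_cv(matrix: MetaboliteMatrix) -> pd.Series:
    """Per-feature coefficient of variation (sd/mean) over sQC injections.

    Features whose sQC mean is zero get CV = NaN (undefined).
    """
    q = matrix.sqc
    if len(q) < 2:
        raise ValueError("CV requires >= 2 sQC injections")
    mean = q.mean(axis=0)
    sd = q.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return cv.rename("cv")


def cv_filter(
    matrix: MetaboliteMatrix, threshold: float = 0.30
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Drop features whose sQC CV exceeds `threshold` (default 30%).

    Returns the filtered matrix and a report listing every feature with its
    CV, whether it was removed, and why. Features with undefined CV (sQC
    mean zero) are removed with reason "undefined CV". Idempotent: refiltering
    a filtered matrix removes nothing.
    """
    cv = qc_cv(matrix)
    keep = cv <= threshold  # NaN compares False -> removed
    reason = np.where(cv.isna(), "undefined CV", np.where(keep, "", "CV above threshold"))
    report = pd.DataFrame({"cv": cv, "removed": ~keep, "reason": reason})
    kept = cv.index[keep]
    out = MetaboliteMatrix(
        matrix.intensities[kept].copy(),
        matrix.sample_meta.copy(),
        matrix.feature_meta.loc[kept].copy(),
        cv[keep],
    )
    return out, report


def rf_impute(
    matrix: MetaboliteMatrix,
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int | None = 0,
) -> MetaboliteMatrix:
    """Impute missing intensities by iterative random-forest regression.

    missForest-style scheme: missing cells start at the feature median;
    then, feature by feature (fewest missing first), each feature with
    missing cells is regressed on all other features by a random forest
    trained on its observed rows, and its missing cells are replaced by
    forest predictions. Iterations stop when the normalised change in the
    imputed cells rises, or at `max_iter`; the previous iterate is returned
    in the former case. Observed cells are never altered.
    """
    X = matrix.intensities.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return matrix.copy()
    feat_all = miss.all(axis=0)
    if feat_all.any():
        bad = list(matrix.intensities.columns[feat_all])
        raise ValueError(f"features entirely missing, cannot impute: {bad}")
    samp_all = miss.all(axis=1)
    if samp_all.any():
        bad = list(matrix.intensities.index[samp_all])
        raise ValueError(f"samples entirely missing, cannot impute: {bad}")

    med = np.nanmedian(X, axis=0)
    X[miss] = np.take(med, np.where(miss)[1])

    order = np.argsort(miss.sum(axis=0))
    order = [j for j in order if miss[:, j].any()]
    rng = np.random.default_rng(seed)
    prev = None
    prev_delta = np.inf
    for _ in range(max_iter):
        before = X[miss].copy()
        for j in order:
            obs = ~miss[:, j]
            other = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[obs][:, other], X[obs, j])
            X[~obs, j] = rf.predict(X[~obs][:, other])
        delta = float(np.sum((X[miss] - before) ** 2)) / max(
            float(np.sum(X[miss] ** 2)), 1e-300
        )
        if delta >= prev_delta:
            X[miss] = prev  # change rose: keep previous iterate
            break
        prev = X[miss].copy()
        prev_delta = delta
        if delta == 0.0:
            break

    out = matrix.copy()
    vals = out.intensities.to_numpy(dtype=float)
    vals[miss] = np.clip(X[miss], 0.0, None)
    out.intensities = pd.DataFrame(
        vals, index=matrix.intensities.index, columns=matrix.intensities.columns
    )
    return out
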