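"""Diet-metabolome association by repeated double cross-validated random
forest with internal variable selection, permutation testing of Q2, and
partial-Spearman validation of selected features.

The rdCV scheme: outer folds are held out entirely; within each outer
training set an inner cross-validation drives recursive variable
elimination by random-forest importance, choosing the minimal-optimal
feature count; a forest refit on the outer training set at that count
predicts the held-out fold. Q2 = 1 - PRESS/TSS on the out-of-fold
predictions, averaged over repetitions. Held-out samples never inform
tuning or training, so Q2 is not optimistic. Models with Q2 above a
threshold (default 0.15) proceed to a permutation test of Q2; features
from passing models are validated by covariate-adjusted partial Spearman
correlation with their exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .risk import build_covariate_design

Q2_THRESHOLD = 0.15  # models below this are not considered informative


@dataclass
class RdcvSettings:
    """Tuning of the repeated double cross-validation."""

    n_rep: int = 10
    n_outer: int = 6
    n_inner: int = 5
    var_ratio: float = 0.75  # fraction of features kept per elimination step
    n_trees: int = 300
    min_features: int = 2
    min_samples: int = 50

    def __post_init__(self):
        if not (0 < self.var_ratio < 1):
            raise ValueError("var_ratio must lie in (0, 1)")
        if self.n_outer < 2 or self.n_inner < 2 or self.n_rep < 1:
            raise ValueError("fold and repetition counts must be >= 2 (reps >= 1)")


@dataclass
class RdcvModel:
    """Result of one rdCV random-forest regression."""

    exposure: str
    q2: float  # mean over repetitions
    q2_per_rep: list[float]
    selected_features: list[str]  # consensus minimal-optimal set
    selection_freq: pd.Series  # per feature, fraction of outer models selecting it
    settings: RdcvSettings
    n_samples: int
    fold_log: list[dict] = field(default_factory=list)
    permutation_p: float | None = None
    permutation_p_parametric: float | None = None
    permuted_q2: list[float] = field(default_factory=list)


@dataclass
class AssociationRecord:
    """Partial Spearman correlation of one feature with one exposure."""

    feature: str
    exposure: str
    rho: float
    p: float
    n: int
    covariates: list[str]


def _q2(y: np.ndarray, yhat: np.ndarray) -> float:
    press = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def _feature_counts(p: int, ratio: float, floor: int) -> list[int]:
    counts = [p]
    while counts[-1] > floor:
        nxt = max(floor, int(np.floor(counts[-1] * ratio)))
        if nxt == counts[-1]:
            nxt -= 1
        counts.append(max(nxt, floor))
        if counts[-1] == floor:
            break
    return counts


def _folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(idx, k)]


def rdcv_rf(
    features: pd.DataFrame,
    exposure: pd.Series,
    settings: RdcvSettings | None = None,
    seed: int | None = 0,
    exposure_name: str | None = None,
) -> RdcvModel:
    """Repeated double cross-validated RF regression with recursive
    importance-based variable elimination.

    `features` is samples x features (complete); `exposure` the continuous
    response aligned on the same index. Returns the model summary with Q2
    on out-of-fold predictions, the consensus minimal-optimal feature set
    (features selected in at least half of the outer-fold models), and a
    log of fold assignments for leakage auditing.
    """
    settings = settings or RdcvSettings()
    if not features.index.equals(exposure.index):
        exposure = exposure.reindex(features.index)
    X = features.to_numpy(dtype=float)
    y = exposure.to_numpy(dtype=float)
    n, p = X.shape
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("rdcv_rf requires complete data; impute first")
    if n < settings.min_samples:
        raise ValueError(f"need >= {settings.min_samples} samples, got {n}")
    if p < 10:
        raise ValueError(f"need >= 10 features, got {p}")
    if np.std(y) == 0:
        raise ValueError("response is constant")
    if n // settings.n_outer < 5:
        raise ValueError("outer folds would have < 5 samples; reduce n_outer")

    rng = np.random.default_rng(seed)
    names = np.array(features.columns)
    counts = _feature_counts(p, settings.var_ratio, settings.min_features)

    q2_per_rep: list[float] = []
    sel_counts = np.zeros(p)
    n_models = 0
    fold_log: list[dict] = []
    for rep in range(settings.n_rep):
        outer = _folds(n, settings.n_outer, rng)
        oof = np.full(n, np.nan)
        for o, test_idx in enumerate(outer):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            fold_log.append(
                {"rep": rep, "outer": o, "test": test_idx.tolist(), "train": train_idx.tolist()}
            )
            Xtr, ytr = X[train_idx], y[train_idx]
            inner = _folds(len(train_idx), settings.n_inner, rng)

            active = np.arange(p)
            step_mse = []
            step_sets = []
            for c in counts:
                if c < len(active):
                    # keep the c most important features from the previous step
                    active = active[np.argsort(-imp)[:c]]
                preds = np.full(len(train_idx), np.nan)
                imp = np.zeros(len(active))
                for val_idx in inner:
                    fit_idx = np.setdiff1d(np.arange(len(train_idx)), val_idx)
                    rf = RandomForestRegressor(
                        n_estimators=settings.n_trees,
                        max_features=1.0 / 3,
                        random_state=int(rng.integers(2**31 - 1)),
                        n_jobs=1,
                    )
                    rf.fit(Xtr[fit_idx][:, active], ytr[fit_idx])
                    preds[val_idx] = rf.predict(Xtr[val_idx][:, active])
                    imp += rf.feature_importances_
                step_mse.append(float(np.mean((ytr - preds) ** 2)))
                step_sets.append(active.copy())
            # minimal-optimal: the smallest feature count attaining the
            # minimum inner validation error
            best = int(np.argmin(step_mse[::-1]))
            best = len(step_mse) - 1 - best
            chosen = step_sets[best]
            rf = RandomForestRegressor(
                n_estimators=settings.n_trees,
                max_features=1.0 / 3,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(Xtr[:, chosen], ytr)
            oof[test_idx] = rf.predict(X[test_idx][:, chosen])
            sel_counts[chosen] += 1
            n_models += 1
        q2_per_rep.append(_q2(y, oof))

    freq = pd.Series(sel_counts / n_models, index=features.columns, name="selection_freq")
    selected = list(freq.index[freq >= 0.5])
    return RdcvModel(
        exposure=exposure_name or (exposure.name or "exposure"),
        q2=float(np.mean(q2_per_rep)),
        q2_per_rep=[float(v) for v in q2_per_rep],
        selected_features=selected,
        selection_freq=freq,
        settings=settings,
        n_samples=n,
        fold_log=fold_log,
    )


def permutation_test(
    features: pd.DataFrame,
    exposure: pd.Series,
    settings: RdcvSettings | None = None,
    n_perm: int = 50,
    seed: int | None = 0,
    observed: RdcvModel | None = None,
) -> RdcvModel:
    """Permutation test of Q2: refit the full rdCV under `n_perm` random
    permutations of the response.

    Empirical p = (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1), bounded below
    by 1/(n_perm+1). The parametric p comes from a normal fit to the
    permuted-Q2 null and can fall far below that bound. Returns the
    observed model with both p values and the null Q2 values attached.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = rdcv_rf(
            features, exposure, settings, seed=int(rng.integers(2**31 - 1))
        )
    null = []
    y = exposure.to_numpy(dtype=float)
    for _ in range(n_perm):
        y_perm = pd.Series(rng.permutation(y), index=features.index, name=exposure.name)
        m = rdcv_rf(features, y_perm, settings, seed=int(rng.integers(2**31 - 1)))
        null.append(m.q2)
    null_arr = np.array(null)
    emp = (1.0 + int(np.sum(null_arr >= observed.q2))) / (n_perm + 1.0)
    mu, sd = float(null_arr.mean()), float(null_arr.std(ddof=1))
    par = float(stats.norm.sf(observed.q2, loc=mu, scale=sd)) if sd > 0 else (
        0.0 if observed.q2 > mu else 1.0
    )
    observed.permutation_p = float(emp)
    observed.permutation_p_parametric = par
    observed.permuted_q2 = [float(v) for v in null]
    return observed


def partial_spearman(
    feature: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    cohort: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    feature_name: str | None = None,
    exposure_name: str | None = None,
    min_n: int = 20,
) -> AssociationRecord:
    """Partial Spearman correlation of a feature with a dietary exposure.

    Feature, exposure and every covariate column are rank-transformed
    (average ranks for ties; indicator columns are unchanged by ranking up
    to an affine map), the feature and exposure ranks are residualised on
    the covariate ranks (plus intercept), and rho is the Pearson
    correlation of the residuals — the standard rank-based partial
    correlation. The p value uses the t approximation with n - 2 - q
    degrees of freedom, q the number of covariate columns. With no
    covariates this reduces to the ordinary Spearman correlation. A
    zero-variance residual yields an explicit null record (rho = NaN)
    rather than an exception.
    """
    if covariates is None and cohort is not None:
        names = covariate_names or [c for c in
                                    ("bmi", "smoking", "activity", "education",
                                     "energy_kcal", "alcohol_cat")
                                    if c in cohort.columns]
        ename = exposure_name or exposure.name or ""
        if "alcohol" in str(ename).lower():
            names = [c for c in names if c != "alcohol_cat"]
        covariates = build_covariate_design(cohort, names)
    if covariates is None:
        covariates = pd.DataFrame(index=feature.index)
    covariates = covariates.reindex(feature.index)
    exposure = exposure.reindex(feature.index)

    df = pd.concat([feature.rename("__f__"), exposure.rename("__e__"), covariates], axis=1)
    df = df.dropna()
    n = len(df)
    if n < min_n:
        raise ValueError(f"need >= {min_n} complete observations, got {n}")
    q = covariates.shape[1]
    rf = stats.rankdata(df["__f__"])
    re_ = stats.rankdata(df["__e__"])
    Zraw = df.iloc[:, 2:].to_numpy(dtype=float)
    Zrank = (
        np.column_stack([stats.rankdata(Zraw[:, j]) for j in range(Zraw.shape[1])])
        if Zraw.shape[1]
        else Zraw
    )
    Z = np.column_stack([np.ones(n), Zrank])
    rf_res = rf - Z @ np.linalg.lstsq(Z, rf, rcond=None)[0]
    re_res = re_ - Z @ np.linalg.lstsq(Z, re_, rcond=None)[0]
    record = AssociationRecord(
        feature=feature_name or str(feature.name),
        exposure=exposure_name or str(exposure.name),
        rho=np.nan,
        p=np.nan,
        n=n,
        covariates=list(covariates.columns),
    )
    sf, se_ = float(np.std(rf_res)), float(np.std(re_res))
    # ranks live on a scale of ~n, so residual SDs below n * 1e-8 are
    # numerically zero (e.g. the variable coincides with a covariate)
    if sf <= 1e-8 * n or se_ <= 1e-8 * n:
        return record  # explicit null: residual variance vanished
    rho = float(np.dot(rf_res, re_res) / (n * sf * se_))
    rho = float(np.clip(rho, -1.0, 1.0))
    dof = n - 2 - q
    if dof <= 0:
        return record
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(dof / (1.0 - rho**2))
        p = 2.0 * float(stats.t.sf(abs(t), dof))
    record.rho = rho
    record.p = p
    return record


def select_diet_features(
    models: list[RdcvModel],
    associations: list[AssociationRecord],
    q2_thresh: float = Q2_THRESHOLD,
    p_thresh: float = 0.05,
    spearman_p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Unique diet-reflecting features with their exposure tags.

    A model contributes when its Q2 exceeds `q2_thresh` and its empirical
    permutation p is below `p_thresh`; its selected features are kept when
    the matching partial-Spearman record is significant. Features selected
    by several exposures collapse to one row with all tags.
    """
    if not (0 < p_thresh < 1) or not (0 < spearman_p_thresh < 1):
        raise ValueError("p thresholds must lie in (0, 1)")
    if not (0 < q2_thresh < 1):
        raise ValueError("q2_thresh must lie in (0, 1)")
    assoc = {(a.feature, a.exposure): a for a in associations}
    tags: dict[str, list[str]] = {}
    for m in models:
        if m.q2 <= q2_thresh:
            continue
        if m.permutation_p is None or m.permutation_p >= p_thresh:
            continue
        for f in m.selected_features:
            a = assoc.get((f, m.exposure))
            if a is None or not np.isfinite(a.p) or a.p >= spearman_p_thresh:
                continue
            tags.setdefault(f, [])
            if m.exposure not in tags[f]:
                tags[f].append(m.exposure)
    return pd.DataFrame(
        {
            "feature": list(tags),
            "exposures": [";".join(v) for v in tags.values()],
            "n_exposures": [len(v) for v in tags.values()],
        }
    ).set_index("feature")
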