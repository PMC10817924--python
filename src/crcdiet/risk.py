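"""Conditional logistic regression for matched 1:1 case-control pairs.

For 1:1 matching the conditional likelihood is

    sum over pairs of [ b'(x_case - x_control) - log(1 + exp(b'(x_case - x_control))) ]

which is exactly a no-intercept logistic regression on within-pair
covariate differences with all responses equal to 1; that equivalence is
how the model is fit here. Exposures are standardised to unit SD over the
analysed participants, so odds ratios are per 1-SD increase. Pairs with
any missing covariate are dropped; when alcohol is the exposure the
categorical alcohol covariate is excluded from adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .diet import categorize_alcohol

#: Adjustment set used throughout: BMI, smoking, physical activity,
#: education, total energy and categorical alcohol.
DEFAULT_COVARIATES = ["bmi", "smoking", "activity", "education", "energy_kcal", "alcohol_cat"]

CATEGORICAL = {
    "smoking": ["never", "ex", "current"],
    "activity": ["none", "low", "medium", "high"],
    "education": ["elementary", "secondary", "post-secondary"],
    "alcohol_cat": ["zero", "below", "above"],
}


@dataclass
class RiskEstimate:
    """Per-SD odds ratio with Wald 95% CI for one exposure in one stratum."""

    exposure: str
    stratum: str
    n_pairs: int
    or_: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    stable: bool  # False when fewer than 10 pairs contributed

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "stratum": self.stratum,
            "n_pairs": self.n_pairs,
            "OR": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "stable": self.stable,
        }


def add_alcohol_category(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach the 3-level alcohol covariate derived from g/day and sex."""
    out = cohort.copy()
    out["alcohol_cat"] = categorize_alcohol(cohort["alcohol_g"], cohort["sex"])
    return out


def build_covariate_design(
    cohort: pd.DataFrame, covariates: list[str]
) -> pd.DataFrame:
    """Expand covariates to a numeric design: continuous as-is, categorical
    as indicator contrasts with the first level as reference."""
    parts = []
    for cov in covariates:
        if cov not in cohort.columns:
            raise KeyError(f"covariate {cov!r} not in cohort table")
        col = cohort[cov]
        if cov in CATEGORICAL:
            levels = CATEGORICAL[cov]
            bad = set(col.dropna().unique()) - set(levels)
            if bad:
                raise ValueError(f"covariate {cov!r} has unknown levels {sorted(bad)}")
            for lev in levels[1:]:
                d = (col == lev).astype(float)
                d[col.isna()] = np.nan
                parts.append(d.rename(f"{cov}[{lev}]"))
        else:
            parts.append(pd.to_numeric(col, errors="coerce").rename(cov))
    if not parts:
        return pd.DataFrame(index=cohort.index)
    return pd.concat(parts, axis=1)


def _is_alcohol_exposure(name: str | None) -> bool:
    return name is not None and "alcohol" in name.lower()


def fit_clogit(
    cohort: pd.DataFrame,
    exposure: pd.Series,
    covariates: list[str] | None = None,
    exposure_name: str | None = None,
    stratum: str = "all",
    drop_alcohol_covariate: bool | None = None,
    min_stable_pairs: int = 10,
    standardize: bool = True,
) -> RiskEstimate:
    """Fit the matched-pair conditional logistic model for one exposure.

    With ``standardize=True`` (default) the exposure is scaled to unit SD
    over the analysed participants, so the OR is per 1-SD increase; with
    ``standardize=False`` the OR is per unit of the raw exposure.

    Parameters
    ----------
    cohort : CohortTable with columns pair_id, case, and the covariates.
    exposure : per-participant values aligned to the cohort index.
    covariates : adjustment set; defaults to DEFAULT_COVARIATES filtered to
        the columns present in `cohort`.
    drop_alcohol_covariate : exclude the alcohol covariate; defaults to
        auto-detection from the exposure name (alcohol exposures are not
        adjusted for alcohol).

    Raises
    ------
    ValueError on zero exposure SD, fewer than 2 usable pairs, or complete
    separation (no finite maximiser of the conditional likelihood).
    """
    name = exposure_name or (exposure.name if exposure.name is not None else "exposure")
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in cohort.columns]
    if drop_alcohol_covariate is None:
        drop_alcohol_covariate = _is_alcohol_exposure(name)
    if drop_alcohol_covariate:
        covariates = [c for c in covariates if c != "alcohol_cat"]

    exposure = pd.to_numeric(exposure, errors="coerce").reindex(cohort.index)
    design = build_covariate_design(cohort, covariates)
    work = pd.concat([exposure.rename("__exposure__"), design], axis=1)
    work["__pair__"] = cohort["pair_id"].to_numpy()
    work["__case__"] = cohort["case"].to_numpy()

    # pair-wise deletion: drop pairs with any missing value
    complete_rows = work.drop(columns=["__pair__", "__case__"]).notna().all(axis=1)
    ok_pairs = work.loc[complete_rows, "__pair__"].value_counts()
    ok_pairs = set(ok_pairs.index[ok_pairs == 2])
    work = work[complete_rows & work["__pair__"].isin(ok_pairs)]
    n_pairs = len(ok_pairs)
    if n_pairs < 2:
        raise ValueError(f"only {n_pairs} complete pairs; cannot fit")

    sd = work["__exposure__"].std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError(f"exposure {name!r} has zero SD among analysed participants")
    if standardize:
        work["__exposure__"] = (work["__exposure__"] - work["__exposure__"].mean()) / sd

    cols = ["__exposure__"] + list(design.columns)
    grouped = work.sort_values(["__pair__", "__case__"], ascending=[True, False])
    vals = grouped[cols].to_numpy(dtype=float)
    cases = vals[0::2]  # case first within each pair after the sort
    controls = vals[1::2]
    if not (
        grouped["__case__"].to_numpy()[0::2] == 1
    ).all() or not (grouped["__case__"].to_numpy()[1::2] == 0).all():
        raise ValueError("each pair must contain exactly one case and one control")
    diffs = cases - controls

    if np.ptp(diffs[:, 0]) == 0 and np.all(diffs[:, 0] == 0):
        # no within-pair exposure contrast anywhere: the conditional
        # likelihood is flat in beta, the MLE is exactly 0 (OR = 1)
        return RiskEstimate(
            exposure=name,
            stratum=stratum,
            n_pairs=n_pairs,
            or_=1.0,
            ci_low=0.0,
            ci_high=np.inf,
            p=1.0,
            beta=0.0,
            se=np.inf,
            stable=n_pairs >= min_stable_pairs,
        )

    # drop covariate columns constant within all pairs (e.g. matched
    # factors) and columns (near-)collinear with those already kept, so
    # small strata with degenerate contrasts stay estimable
    keep = [0]
    for j in range(1, diffs.shape[1]):
        if np.ptp(diffs[:, j]) == 0:
            continue
        cand = diffs[:, keep + [j]]
        cand = cand / np.linalg.norm(cand, axis=0)
        if np.linalg.svd(cand, compute_uv=False)[-1] > 1e-4:
            keep.append(j)
    D = diffs[:, keep]
    try:
        fit = sm.Logit(np.ones(len(D)), D).fit(disp=0, maxiter=200)
    except Exception as err:  # noqa: BLE001 - statsmodels raises several types
        raise ValueError(
            f"conditional logistic fit failed for {name!r} "
            f"(possible complete separation): {err}"
        ) from err
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    if not np.isfinite(se) or se > 1e3:
        raise ValueError(
            f"complete separation for {name!r}: no finite conditional MLE "
            f"(|beta|={abs(beta):.2f}, se={se:.2f})"
        )
    z = beta / se
    p = 2.0 * float(norm.sf(abs(z)))
    return RiskEstimate(
        exposure=name,
        stratum=stratum,
        n_pairs=n_pairs,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959964 * se)),
        ci_high=float(np.exp(beta + 1.959964 * se)),
        p=p,
        beta=beta,
        se=se,
        stable=n_pairs >= min_stable_pairs,
    )


def _pair_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per pair: pair id, sex, and the case's tumour site."""
    cases = cohort[cohort["case"] == 1]
    return pd.DataFrame(
        {
            "pair_id": cases["pair_id"].to_numpy(),
            "sex": cases["sex"].to_numpy(),
            "site": cases["tumor_site"].replace("", "unknown").to_numpy(),
        }
    )


def stratified_analysis(
    cohort: pd.DataFrame,
    exposure: pd.Series,
    covariates: list[str] | None = None,
    strata: tuple[str, ...] = ("sex",),
    exposure_name: str | None = None,
    **kwargs,
) -> list[RiskEstimate]:
    """Per-stratum conditional-logistic estimates.

    `strata` may contain "sex", "site", or both (crossed). Sex strata keep
    every pair (pairs are sex-matched); site strata keep the pairs whose
    case has that tumour site, excluding unknown-site pairs. Strata with
    fewer than 10 pairs are returned flagged unstable, not suppressed.
    """
    unknown = set(strata) - {"sex", "site"}
    if unknown:
        raise ValueError(f"unknown strata {sorted(unknown)}; use 'sex' and/or 'site'")
    pairs = _pair_table(cohort)
    groups: list[tuple[str, pd.Series]] = []
    if "sex" in strata and "site" in strata:
        for s in ("F", "M"):
            for site in ("proximal", "distal", "rectum"):
                groups.append(
                    (f"sex={s},site={site}", (pairs["sex"] == s) & (pairs["site"] == site))
                )
    elif "sex" in strata:
        for s in ("F", "M"):
            groups.append((f"sex={s}", pairs["sex"] == s))
    elif "site" in strata:
        for site in ("proximal", "distal", "rectum"):
            groups.append((f"site={site}", pairs["site"] == site))
    else:
        raise ValueError("strata must name at least one of 'sex', 'site'")

    out = []
    for label, mask in groups:
        pair_ids = set(pairs.loc[mask, "pair_id"])
        sub = cohort[cohort["pair_id"].isin(pair_ids)]
        if sub.empty:
            continue
        est = fit_clogit(
            sub,
            exposure.reindex(sub.index),
            covariates=covariates,
            exposure_name=exposure_name or exposure.name,
            stratum=label,
            **kwargs,
        )
        out.append(est)
    return out


def risk_table(estimates: list[RiskEstimate]) -> pd.DataFrame:
    """Tidy table of estimates (exposure, stratum, n_pairs, OR, CI, p)."""
    return pd.DataFrame([e.to_dict() for e in estimates])
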