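"""Conditional logistic regression: closed forms, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from crcdiet import (
    add_alcohol_category,
    fit_clogit,
    generate_cohort,
    stratified_analysis,
)
from crcdiet.simulate import PlantedFactor, SimConfig


def discordant_cohort(case_exposed=10, control_exposed=5):
    rows = []
    for i in range(case_exposed + control_exposed):
        exp_case = 1.0 if i < case_exposed else 0.0
        rows.append({"pair_id": f"p{i:02d}", "case": 1, "exp": exp_case})
        rows.append({"pair_id": f"p{i:02d}", "case": 0, "exp": 1.0 - exp_case})
    return pd.DataFrame(rows, index=[f"i{j:03d}" for j in range(2 * len(rows) // 2)])


@pytest.fixture(scope="module")
def adjusted_cohort():
    config = SimConfig(
        n_pairs=500,
        n_foods=6,
        planted_factors=[PlantedFactor("A", [0, 1, 2], [0.8, 0.7, 0.6])],
        planted_log_or={"A": float(np.log(0.8))},
        seed=11,
    )
    cohort, _, truth = generate_cohort(config)
    cohort = add_alcohol_category(cohort)
    return cohort, truth.exposures["A"]


class TestClosedForms:
    def test_discordant_pairs_give_or_two(self):
        """10 pairs with only the case exposed vs 5 with only the control
        exposed: the conditional MLE is the discordant-pair ratio 10/5."""
        cohort = discordant_cohort()
        est = fit_clogit(
            cohort, cohort["exp"], covariates=[], standardize=False, exposure_name="binary"
        )
        assert est.or_ == pytest.approx(2.0, abs=1e-6)

    def test_exposure_constant_within_pairs_gives_or_one_exactly(self):
        cohort = discordant_cohort()
        same = pd.Series(np.repeat(np.arange(15.0), 2), index=cohort.index)
        est = fit_clogit(cohort, same, covariates=[], exposure_name="flat")
        assert est.or_ == 1.0 and est.beta == 0.0


class TestOracleEquivalence:
    @staticmethod
    def _design(cohort, exposure):
        scaled = cohort.copy()
        for c in ("bmi", "energy_kcal"):  # unit scale so every optimiser converges
            scaled[c] = (scaled[c] - scaled[c].mean()) / scaled[c].std(ddof=1)
        x = (exposure - exposure.mean()) / exposure.std(ddof=1)
        X = pd.DataFrame(
            {"x": x, "bmi": scaled["bmi"], "energy_kcal": scaled["energy_kcal"]}
        )
        return scaled, X

    def test_matches_exact_conditional_likelihood_maximiser(self, adjusted_cohort):
        """Dual route: the pair-difference fit must equal a direct numeric
        maximisation of the exact 1:1 conditional likelihood."""
        from scipy import optimize

        cohort, exposure = adjusted_cohort
        scaled, X = self._design(cohort, exposure)
        est = fit_clogit(scaled, exposure, covariates=["bmi", "energy_kcal"],
                         exposure_name="A")
        df = pd.concat([X, cohort[["pair_id", "case"]]], axis=1).sort_values(
            ["pair_id", "case"], ascending=[True, False]
        )
        D = df[["x", "bmi", "energy_kcal"]].to_numpy()
        diffs = D[0::2] - D[1::2]

        def negll(beta):
            eta = diffs @ beta
            return np.sum(np.logaddexp(0.0, -eta)), -diffs.T @ (1 / (1 + np.exp(eta)))

        res = optimize.minimize(negll, np.zeros(3), jac=True, method="BFGS",
                                options={"gtol": 1e-12})
        assert est.beta == pytest.approx(res.x[0], abs=1e-8)

    def test_close_to_statsmodels_conditional_logit(self, adjusted_cohort):
        """Cross-check against the generic conditional-likelihood fitter
        (its BFGS stops a little earlier, hence the looser tolerance)."""
        cohort, exposure = adjusted_cohort
        scaled, X = self._design(cohort, exposure)
        est = fit_clogit(scaled, exposure, covariates=["bmi", "energy_kcal"],
                         exposure_name="A")
        ref = sm.ConditionalLogit(
            cohort["case"].to_numpy(), X.to_numpy(), groups=cohort["pair_id"].to_numpy()
        ).fit(disp=0, maxiter=500)
        assert est.beta == pytest.approx(ref.params[0], abs=1e-4)
        assert est.se == pytest.approx(ref.bse[0], rel=1e-3)


class TestInvariances:
    def test_pair_constant_covariate_changes_nothing(self, adjusted_cohort):
        cohort, exposure = adjusted_cohort
        base = fit_clogit(cohort, exposure, covariates=["bmi"], exposure_name="A")
        withage = fit_clogit(cohort, exposure, covariates=["bmi", "age"], exposure_name="A")
        assert withage.beta == pytest.approx(base.beta, abs=1e-12)

    def test_case_control_swap_negates_beta(self, adjusted_cohort):
        cohort, exposure = adjusted_cohort
        swapped = cohort.copy()
        swapped["case"] = 1 - swapped["case"]
        a = fit_clogit(cohort, exposure, covariates=["bmi"], exposure_name="A")
        b = fit_clogit(swapped, exposure, covariates=["bmi"], exposure_name="A")
        assert b.beta == pytest.approx(-a.beta, abs=1e-9)

    def test_per_sd_or_invariant_to_linear_rescaling(self, adjusted_cohort):
        cohort, exposure = adjusted_cohort
        a = fit_clogit(cohort, exposure, covariates=["bmi"], exposure_name="A")
        b = fit_clogit(cohort, 3.7 * exposure + 2.0, covariates=["bmi"], exposure_name="A")
        assert b.or_ == pytest.approx(a.or_, rel=1e-10)

    def test_alcohol_exposure_drops_alcohol_covariate(self, adjusted_cohort):
        cohort, _ = adjusted_cohort
        auto = fit_clogit(cohort, cohort["alcohol_g"], exposure_name="total_alcohol")
        explicit = fit_clogit(
            cohort,
            cohort["alcohol_g"],
            covariates=["bmi", "smoking", "activity", "education", "energy_kcal"],
            exposure_name="total_alcohol",
            drop_alcohol_covariate=False,
        )
        assert auto.beta == pytest.approx(explicit.beta, abs=1e-12)

    def test_zero_sd_exposure_rejected(self, adjusted_cohort):
        cohort, _ = adjusted_cohort
        flat = pd.Series(1.0, index=cohort.index)
        with pytest.raises(ValueError, match="zero SD"):
            fit_clogit(cohort, flat, covariates=[], exposure_name="flat")

    def test_missing_covariates_drop_whole_pairs(self, adjusted_cohort):
        cohort, exposure = adjusted_cohort
        broken = cohort.copy()
        broken.loc[broken.index[0], "bmi"] = np.nan  # knocks out one pair
        est = fit_clogit(broken, exposure, covariates=["bmi"], exposure_name="A")
        assert est.n_pairs == 499


class TestStratified:
    def test_sex_strata_partition_all_pairs(self, adjusted_cohort):
        cohort, exposure = adjusted_cohort
        ests = stratified_analysis(cohort, exposure, covariates=["bmi"],
                                   strata=("sex",), exposure_name="A")
        assert sum(e.n_pairs for e in ests) == 500

    def test_site_strata_exclude_unknown(self, adjusted_cohort):
        cohort, exposure = adjusted_cohort
        ests = stratified_analysis(cohort, exposure, covariates=["bmi"],
                                   strata=("site",), exposure_name="A")
        cases = cohort[cohort["case"] == 1]
        n_unknown = (cases["tumor_site"] == "unknown").sum() + (cases["tumor_site"] == "").sum()
        assert sum(e.n_pairs for e in ests) == 500 - n_unknown

    def test_small_strata_flagged_unstable_not_dropped(self):
        config = SimConfig(
            n_pairs=40,
            n_foods=4,
            planted_factors=[PlantedFactor("A", [0, 1], [0.8, 0.7])],
            seed=2,
        )
        cohort, _, truth = generate_cohort(config)
        ests = stratified_analysis(
            cohort, truth.exposures["A"], covariates=[], strata=("site",),
            exposure_name="A",
        )
        small = [e for e in ests if e.n_pairs < 10]
        assert all(not e.stable for e in small)

    def test_planted_site_specific_effect_detected_in_right_stratum(self):
        """Effect planted only for distal-site pairs: the distal CI should
        exclude 1 more often than the proximal CI does (majority of seeds)."""
        distal_hit, proximal_hit = 0, 0
        n_seeds = 11
        for seed in range(n_seeds):
            config = SimConfig(
                n_pairs=1000,
                n_foods=4,
                planted_factors=[PlantedFactor("A", [0, 1], [0.8, 0.7])],
                site_log_or={"A": {"distal": float(np.log(0.6))}},
                seed=seed,
            )
            cohort, _, truth = generate_cohort(config)
            ests = {
                e.stratum: e
                for e in stratified_analysis(
                    cohort, truth.exposures["A"], covariates=[], strata=("site",),
                    exposure_name="A",
                )
            }
            d, p = ests["site=distal"], ests["site=proximal"]
            distal_hit += not (d.ci_low <= 1.0 <= d.ci_high)
            proximal_hit += not (p.ci_low <= 1.0 <= p.ci_high)
        assert distal_hit > n_seeds / 2
        assert proximal_hit < n_seeds / 2
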