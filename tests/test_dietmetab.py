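"""rdCV random forest, permutation testing, partial Spearman, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcdiet import (
    RdcvModel,
    RdcvSettings,
    partial_spearman,
    permutation_test,
    rdcv_rf,
    select_diet_features,
)
from crcdiet.dietmetab import AssociationRecord
from crcdiet.scenarios import confounded_triple, rdcv_null_data

FAST = RdcvSettings(
    n_rep=1, n_outer=4, n_inner=3, var_ratio=0.4, n_trees=30, min_samples=40
)


def perfect_signal_data(seed=0, n=90, p=12):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"f{j + 1:02d}" for j in range(p)]
    )
    y = X["f01"].rename("y")  # response is an exact copy of one feature
    return X, y


class TestRdcvRf:
    def test_perfect_signal_q2_high_and_feature_always_selected(self):
        # forests need enough samples to resolve an exact copy; 120 samples
        # and 80 trees put the ceiling comfortably above Q2 = 0.9
        X, y = perfect_signal_data(n=120)
        strong = RdcvSettings(
            n_rep=1, n_outer=4, n_inner=3, var_ratio=0.4, n_trees=80, min_samples=40
        )
        m = rdcv_rf(X, y, strong, seed=1)
        assert m.q2 >= 0.9
        assert "f01" in m.selected_features
        assert m.selection_freq["f01"] == 1.0

    def test_null_response_mean_q2_nonpositive(self):
        q2s = []
        for seed in range(10):
            X, y = rdcv_null_data(seed)
            q2s.append(rdcv_rf(X, y, FAST, seed=seed).q2)
        assert np.mean(q2s) <= 0.0

    def test_outer_fold_hygiene(self):
        """No held-out sample index may appear in its own training set, and
        the outer folds of one repetition must partition the samples."""
        X, y = perfect_signal_data()
        m = rdcv_rf(X, y, FAST, seed=2)
        by_rep = {}
        for entry in m.fold_log:
            assert not set(entry["test"]) & set(entry["train"])
            assert sorted(entry["test"] + entry["train"]) == list(range(len(X)))
            by_rep.setdefault(entry["rep"], []).extend(entry["test"])
        for rep_tests in by_rep.values():
            assert sorted(rep_tests) == list(range(len(X)))

    def test_constant_response_rejected(self):
        X, _ = perfect_signal_data()
        flat = pd.Series(1.0, index=X.index)
        with pytest.raises(ValueError, match="constant"):
            rdcv_rf(X, flat, FAST, seed=0)

    def test_too_small_folds_rejected(self):
        X, y = perfect_signal_data(n=40)
        bad = RdcvSettings(n_rep=1, n_outer=10, n_inner=3, var_ratio=0.4,
                           n_trees=10, min_samples=30)
        with pytest.raises(ValueError, match="folds"):
            rdcv_rf(X, y, bad, seed=0)


class TestPermutation:
    def test_strong_signal_attains_rank_lower_bound(self):
        X, y = perfect_signal_data()
        m = permutation_test(X, y, FAST, n_perm=20, seed=5)
        assert m.permutation_p == pytest.approx(1.0 / 21.0)
        assert m.permutation_p_parametric < 1e-4
        assert len(m.permuted_q2) == 20

    def test_minimum_permutation_count_enforced(self):
        X, y = perfect_signal_data()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(X, y, FAST, n_perm=5, seed=0)


class TestPartialSpearman:
    def test_no_covariates_equals_ordinary_spearman(self, rng):
        f = pd.Series(rng.standard_normal(100), name="f")
        e = pd.Series(rng.standard_normal(100), name="e")
        rec = partial_spearman(f, e)
        ref = stats.spearmanr(f, e)
        assert rec.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert rec.p == pytest.approx(ref.pvalue, rel=0.05)

    def test_matches_pingouin_with_covariates(self, rng):
        pg = pytest.importorskip("pingouin")
        z = rng.standard_normal(150)
        f = pd.Series(z + 0.5 * rng.standard_normal(150), name="f")
        e = pd.Series(z + 0.5 * rng.standard_normal(150), name="e")
        rec = partial_spearman(f, e, covariates=pd.DataFrame({"z": z}))
        ref = pg.partial_corr(
            pd.DataFrame({"f": f, "e": e, "z": z}), x="f", y="e", covar="z",
            method="spearman",
        )
        assert rec.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_monotone_identity_reaches_one(self, rng):
        x = rng.standard_normal(500)
        f = pd.Series(np.exp(x), name="f")  # strictly monotone transform
        e = pd.Series(x, name="e")
        cov = pd.DataFrame({"z": rng.standard_normal(500)})
        rec = partial_spearman(f, e, covariates=cov)
        assert rec.rho >= 0.99

    def test_confounding_removed(self):
        feature, exposure, cov = confounded_triple(seed=0, n=1000)
        marginal = stats.spearmanr(feature, exposure).statistic
        rec = partial_spearman(feature, exposure, covariates=cov)
        assert abs(marginal) > 0.8
        assert abs(rec.rho) < 0.1

    def test_zero_residual_variance_returns_explicit_null(self):
        z = pd.Series(np.arange(30, dtype=float), name="z")
        rec = partial_spearman(
            z.rename("f"), z.rename("e"), covariates=pd.DataFrame({"z": z})
        )
        assert np.isnan(rec.rho) and np.isnan(rec.p)

    def test_minimum_n_enforced(self, rng):
        s = pd.Series(rng.standard_normal(10), name="s")
        with pytest.raises(ValueError, match="complete observations"):
            partial_spearman(s, s.rename("t"))


def _model(exposure, q2, p, features):
    return RdcvModel(
        exposure=exposure, q2=q2, q2_per_rep=[q2], selected_features=features,
        selection_freq=pd.Series(dtype=float), settings=FAST, n_samples=100,
        permutation_p=p,
    )


def _assoc(feature, exposure, p=0.001):
    return AssociationRecord(feature, exposure, rho=0.4, p=p, n=100, covariates=[])


class TestSelectDietFeatures:
    def test_nothing_passes_gives_empty_set(self):
        models = [_model("a", 0.05, 0.01, ["f1"]), _model("b", 0.4, 0.5, ["f2"])]
        out = select_diet_features(models, [_assoc("f1", "a"), _assoc("f2", "b")])
        assert out.empty

    def test_shared_feature_collapses_with_both_tags(self):
        models = [_model("a", 0.4, 0.01, ["f1"]), _model("b", 0.3, 0.01, ["f1", "f2"])]
        assoc = [_assoc("f1", "a"), _assoc("f1", "b"), _assoc("f2", "b")]
        out = select_diet_features(models, assoc)
        assert len(out) == 2
        assert out.loc["f1", "exposures"] == "a;b"
        assert out.loc["f1", "n_exposures"] == 2

    def test_spearman_validation_gates_features(self):
        models = [_model("a", 0.4, 0.01, ["f1", "f2"])]
        assoc = [_assoc("f1", "a", p=0.001), _assoc("f2", "a", p=0.9)]
        out = select_diet_features(models, assoc)
        assert list(out.index) == ["f1"]

    @pytest.mark.parametrize("loose,tight", [((0.2, 0.1), (0.3, 0.01))])
    def test_relaxing_thresholds_never_shrinks_selection(self, loose, tight):
        models = [
            _model("a", 0.25, 0.05 - 1e-9, ["f1"]),
            _model("b", 0.35, 0.001, ["f2"]),
        ]
        assoc = [_assoc("f1", "a"), _assoc("f2", "b")]
        small = select_diet_features(models, assoc, q2_thresh=tight[0], p_thresh=tight[1])
        big = select_diet_features(models, assoc, q2_thresh=loose[0], p_thresh=loose[1])
        assert set(small.index) <= set(big.index)
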