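"""ML EFA, oblimin rotation, Tucker congruence, CFA."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from crcdiet import cfa_fit, efa_ml, oblimin_rotate, tucker_phi
from crcdiet.factor import HeywoodWarning, _oblimin_criterion


def planted_two_factor(n=2000, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    p = 12
    Lam = np.zeros((p, 2))
    Lam[:4, 0] = [0.8, 0.7, 0.7, 0.6]
    Lam[6:10, 1] = [0.8, 0.75, 0.7, 0.6]
    z = rng.standard_normal((n, 2))
    X = z @ Lam.T + noise * rng.standard_normal((n, p))
    X += np.sqrt(np.clip(1 - (Lam**2).sum(1) - noise**2, 0.05, None)) * rng.standard_normal((n, p))
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)]), Lam


class TestTuckerPhi:
    def test_self_congruence_is_one(self, rng):
        v = rng.standard_normal(10)
        assert tucker_phi(v, v) == pytest.approx(1.0)
        assert tucker_phi(v, -v) == pytest.approx(-1.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounded_and_scale_invariant(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(8), r.standard_normal(8)
        phi = tucker_phi(a, b)
        assert -1.0 <= phi <= 1.0
        assert tucker_phi(3.7 * a, 0.2 * b) == pytest.approx(phi)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tucker_phi(np.zeros(4), np.ones(4))


class TestEfaMl:
    def test_noiseless_single_factor_recovered_exactly(self, rng):
        lam = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        z = rng.standard_normal(500)
        X = pd.DataFrame(np.outer(z, lam), columns=list("abcde"))
        with pytest.warns(HeywoodWarning):
            sol = efa_ml(X, 1)
        # loadings live in the correlation metric; rescale by the sample SD
        # to compare with the planted covariance-scale vector
        cov_loadings = sol.loadings.iloc[:, 0] * X.std(ddof=1)
        assert abs(tucker_phi(cov_loadings, lam)) == pytest.approx(1.0, abs=1e-6)

    def test_planted_two_factor_recovery(self):
        X, Lam = planted_two_factor()
        sol = efa_ml(X, 2)
        for j in range(2):
            best = max(abs(tucker_phi(sol.loadings.iloc[:, j], Lam[:, l])) for l in range(2))
            assert best >= 0.98

    def test_agrees_with_r_factanal_on_same_correlation_matrix(self, tmp_path):
        """Independent oracle: R stats::factanal on the identical input.

        The unrotated ML solutions are compared through the reproduced
        common-variance matrix Lambda Lambda' (rotation-invariant) and the
        uniquenesses.
        """
        X, _ = planted_two_factor(n=800, seed=3)
        csv = tmp_path / "x.csv"
        X.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            x <- read.csv("{csv}")
            f <- factanal(x, factors = 2, rotation = "none")
            L <- unclass(f$loadings)
            cat(jsonlite::toJSON(list(ll = L %*% t(L), psi = f$uniquenesses)))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        sol = efa_ml(X, 2, rotate=False)
        mine_ll = sol.loadings.to_numpy() @ sol.loadings.to_numpy().T
        assert np.max(np.abs(mine_ll - np.array(ref["ll"]))) < 5e-3
        assert np.max(np.abs(sol.uniquenesses.to_numpy() - np.array(ref["psi"]))) < 5e-3

    def test_degenerate_factor_count_flagged(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 10)))
        with pytest.raises(ValueError, match="degenerate"):
            efa_ml(X, 9)

    def test_missing_data_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 5)))
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            efa_ml(X, 1)


class TestOblimin:
    def test_single_factor_is_identity(self, rng):
        L = rng.standard_normal((8, 1))
        rot, phi = oblimin_rotate(L)
        np.testing.assert_allclose(np.abs(rot), np.abs(L))
        np.testing.assert_allclose(phi, [[1.0]])

    def test_simple_structure_is_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.8, 0.7, 0.6]
        L[3:, 1] = [0.8, 0.7, 0.6]
        f_before = _oblimin_criterion(L, 0.0)[0]
        rot, _ = oblimin_rotate(L)
        f_after = _oblimin_criterion(np.asarray(rot), 0.0)[0]
        assert f_after <= f_before + 1e-10
        assert f_after == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_direct_minimiser(self, rng):
        """Oracle: direct scipy minimisation of the oblimin criterion over
        the oblique rotation matrix, from several random starts."""
        A = rng.standard_normal((10, 3))
        rot, _ = oblimin_rotate(A)
        f_gpa = _oblimin_criterion(np.asarray(rot), 0.0)[0]
        f_before = _oblimin_criterion(A, 0.0)[0]
        assert f_gpa <= f_before + 1e-12

        k = 3

        def crit(t):
            T = t.reshape(k, k)
            T = T / np.sqrt((T**2).sum(axis=0))
            try:
                L = A @ np.linalg.inv(T).T
            except np.linalg.LinAlgError:
                return 1e6
            return _oblimin_criterion(L, 0.0)[0]

        best = np.inf
        for s in range(8):
            r = np.random.default_rng(s)
            t0 = (np.eye(k) + 0.3 * r.standard_normal((k, k))).ravel()
            res = optimize.minimize(crit, t0, method="Nelder-Mead",
                                    options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-10})
            best = min(best, res.fun)
        assert f_gpa == pytest.approx(best, abs=1e-4)


def cfa_two_factor_data(n=1000, seed=1, phi12=0.3):
    rng = np.random.default_rng(seed)
    p = 8
    Lam = np.zeros((p, 2))
    Lam[:4, 0] = [0.8, 0.7, 0.7, 0.6]
    Lam[4:, 1] = [0.8, 0.75, 0.7, 0.6]
    Phi = np.array([[1.0, phi12], [phi12, 1.0]])
    z = rng.multivariate_normal([0, 0], Phi, size=n)
    X = z @ Lam.T + np.sqrt(1 - (Lam**2).sum(1)) * rng.standard_normal((n, p))
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
    structure = {"A": ["v0", "v1", "v2", "v3"], "B": ["v4", "v5", "v6", "v7"]}
    return df, structure, Lam, z


class TestCfa:
    def test_planted_structure_recovered(self):
        df, structure, Lam, z = cfa_two_factor_data()
        fit = cfa_fit(df, structure)
        assert fit.converged
        assert fit.fit_indices["cfi"] >= 0.95
        mine = fit.loadings.to_numpy()
        assert np.max(np.abs(mine[mine != 0] - Lam[Lam != 0])) < 0.1
        # fitted discrepancy can be no worse than at the generating values
        # (the MLE beats the truth on the observed sample)
        S = np.cov(df.to_numpy(), rowvar=False, ddof=1)
        Sigma_true = Lam @ np.array([[1, 0.3], [0.3, 1]]) @ Lam.T + np.diag(
            1 - (Lam**2).sum(1)
        )
        sign, logdet_S = np.linalg.slogdet(S)
        F_true = (
            np.linalg.slogdet(Sigma_true)[1]
            + np.trace(S @ np.linalg.inv(Sigma_true))
            - logdet_S
            - 8
        )
        assert fit.fit_indices["discrepancy"] <= F_true + 1e-8

    def test_self_fit_discrepancy_vanishes(self, rng):
        """Data whose sample covariance equals the model-implied covariance
        exactly must fit with ML discrepancy ~ 0."""
        lam = np.array([0.9, 0.8, 0.7, 0.6])
        Sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
        Z = rng.standard_normal((300, 4))
        Z = Z - Z.mean(0)
        # whiten empirically, then colour by the implied covariance
        W = np.linalg.cholesky(np.linalg.inv(np.cov(Z, rowvar=False, ddof=1)))
        X = Z @ W @ np.linalg.cholesky(Sigma).T
        df = pd.DataFrame(X, columns=list("abcd"))
        fit = cfa_fit(df, {"F": ["a", "b", "c", "d"]})
        assert fit.fit_indices["discrepancy"] == pytest.approx(0.0, abs=1e-6)

    def test_scores_zero_mean_and_track_latents(self):
        df, structure, _, z = cfa_two_factor_data()
        fit = cfa_fit(df, structure)
        assert fit.scores.mean().abs().max() < 1e-12
        assert np.corrcoef(fit.scores["A"], z[:, 0])[0, 1] > 0.85

    def test_absent_food_raises_keyerror(self):
        df, structure, _, _ = cfa_two_factor_data(n=100)
        structure = {"A": ["v0", "v99"], "B": ["v4", "v5"]}
        with pytest.raises(KeyError, match="'A'"):
            cfa_fit(df, structure)

    def test_underidentified_factor_named(self):
        df, _, _, _ = cfa_two_factor_data(n=100)
        with pytest.raises(ValueError, match="'B'"):
            cfa_fit(df, {"A": ["v0", "v1", "v2"], "B": ["v4"]})
        with pytest.raises(ValueError, match="underidentified"):
            cfa_fit(df, {"A": ["v0", "v1"]})
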