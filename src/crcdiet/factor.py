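"""Maximum-likelihood factor analysis primitives.

This module provides the numerical core for dietary-pattern derivation:

* :func:`efa_ml` — exploratory factor analysis by maximum likelihood on the
  sample correlation matrix, profiling out the loadings (Lawley-Maxwell),
  followed by oblimin rotation;
* :func:`oblimin_rotate` — oblique gradient-projection rotation of a
  loading matrix toward simple structure (direct quartimin at gamma=0);
* :func:`cfa_fit` — confirmatory factor analysis with factor variances
  fixed at 1, free oblique factor correlations, ML discrepancy on the
  sample covariance, standard fit indices and regression-method factor
  scores;
* :func:`tucker_phi` — Tucker's congruence coefficient between loading
  vectors, used to decide whether factors from different data halves (or
  different factor counts) represent the same construct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FactorSolution",
    "CfaFit",
    "HeywoodWarning",
    "tucker_phi",
    "efa_ml",
    "oblimin_rotate",
    "cfa_fit",
]

#: Lower bound on uniquenesses; solutions hitting it are Heywood cases.
UNIQUENESS_FLOOR = 0.005


class HeywoodWarning(UserWarning):
    """A uniqueness collapsed to its lower bound (improper solution)."""


def tucker_phi(a, b) -> float:
    """Tucker congruence between two loading vectors.

    phi = a.b / sqrt((a.a)(b.b)); +-1 iff the vectors are proportional.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0 or nb == 0:
        raise ValueError("Tucker congruence undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class FactorSolution:
    """Rotated ML exploratory factor-analysis solution."""

    loadings: pd.DataFrame  # foods x k, oblimin-rotated
    phi: np.ndarray  # k x k factor correlations
    uniquenesses: pd.Series  # per food
    k: int
    criterion: float  # oblimin criterion value at the solution
    discrepancy: float  # ML objective value
    converged: bool
    heywood: bool = False
    dof: int = 0


# ---------------------------------------------------------------------------
# Exploratory ML factor analysis (profile objective over uniquenesses)
# ---------------------------------------------------------------------------


def _efa_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    sc = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(sc, sc)
    ev = np.linalg.eigvalsh(Rstar)[::-1]
    e = ev[k:]
    return float(np.sum(e - np.log(e) - 1.0))


def _efa_loadings(psi: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(sc, sc)
    ev, vec = np.linalg.eigh(Rstar)
    order = np.argsort(ev)[::-1][:k]
    lam = np.sqrt(np.maximum(ev[order] - 1.0, 0.0))
    return (vec[:, order] * lam) * np.sqrt(psi)[:, None]


def _efa_gradient(psi: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    L = _efa_loadings(psi, R, k)
    g = L @ L.T + np.diag(psi) - R
    return np.diag(g) / psi**2


def efa_ml(
    data: pd.DataFrame,
    k: int,
    rotate: bool = True,
    gamma: float = 0.0,
    max_iter: int = 500,
) -> FactorSolution:
    """ML exploratory factor analysis with oblimin rotation.

    Factors the sample correlation matrix of `data` (participants x foods)
    into ``Lambda Phi Lambda' + Psi`` with `k` common factors, maximising
    the normal-theory likelihood by L-BFGS-B over the uniquenesses with the
    loadings profiled out. The unrotated solution is then oblimin-rotated
    (gamma=0 is direct quartimin) unless ``rotate=False`` or k == 1.

    Raises
    ------
    ValueError
        If k is infeasible (model degrees of freedom < 0, i.e. more
        parameters than moments — the degenerate case), a food has zero
        variance, or data contain missing values.
    RuntimeError
        On optimiser non-convergence, with iteration diagnostics.

    Warns
    -----
    HeywoodWarning
        When a uniqueness hits its lower bound; the bounded solution is
        returned (flagged on the result).
    """
    X = np.asarray(data, dtype=float)
    foods = list(data.columns) if isinstance(data, pd.DataFrame) else [
        f"v{i}" for i in range(X.shape[1])
    ]
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("EFA requires complete data (no missing entries)")
    if k < 1 or k >= p:
        raise ValueError(f"factor count k={k} must satisfy 1 <= k < {p} foods")
    dof = ((p - k) ** 2 - (p + k)) // 2
    if dof < 0:
        raise ValueError(
            f"degenerate model: k={k} factors on p={p} variables leaves "
            f"{dof} degrees of freedom (more parameters than correlations)"
        )
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        dead = [foods[i] for i in np.where(sd <= 0)[0]]
        raise ValueError(f"zero-variance foods: {dead}")
    R = np.corrcoef(X, rowvar=False)

    # factanal-style start: psi_i = (1 - k/(2p)) / diag(R^-1)
    start = (1.0 - 0.5 * k / p) / np.diag(np.linalg.inv(R))
    start = np.clip(start, UNIQUENESS_FLOOR, 1.0)
    res = optimize.minimize(
        _efa_objective,
        start,
        args=(R, k),
        jac=_efa_gradient,
        method="L-BFGS-B",
        bounds=[(UNIQUENESS_FLOOR, 1.0)] * p,
        options={"maxiter": max_iter},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise RuntimeError(
            f"EFA did not converge: {res.message} after {res.nit} iterations"
        )
    psi = np.clip(res.x, UNIQUENESS_FLOOR, 1.0)
    heywood = bool(np.any(psi <= UNIQUENESS_FLOOR + 1e-12))
    if heywood:
        warnings.warn(
            "Heywood case: uniqueness at lower bound; solution is improper",
            HeywoodWarning,
            stacklevel=2,
        )
    L = _efa_loadings(psi, R, k)

    if rotate and k >= 2:
        L, phi, crit, _ = _gpa_oblique(L, gamma=gamma)
    else:
        phi = np.eye(k)
        crit = _oblimin_criterion(L, gamma)[0]
    L, phi = _fix_signs(L, phi)
    return FactorSolution(
        loadings=pd.DataFrame(L, index=foods, columns=_factor_names(k)),
        phi=phi,
        uniquenesses=pd.Series(psi, index=foods),
        k=k,
        criterion=crit,
        discrepancy=float(res.fun),
        converged=bool(res.success),
        heywood=heywood,
        dof=dof,
    )


def _factor_names(k: int) -> list[str]:
    return [f"F{j + 1}" for j in range(k)]


def _fix_signs(L: np.ndarray, phi: np.ndarray):
    """Flip factor signs so each column's largest-|loading| entry is positive."""
    L = L.copy()
    phi = phi.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
            phi[j, :] = -phi[j, :]
            phi[:, j] = -phi[:, j]
    return L, phi


# ---------------------------------------------------------------------------
# Oblimin rotation by gradient projection
# ---------------------------------------------------------------------------


def _oblimin_criterion(L: np.ndarray, gamma: float):
    """Oblimin criterion value and gradient at loadings L."""
    p, k = L.shape
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    M = L2 - gamma * L2.mean(axis=0, keepdims=True)
    M = M @ N
    f = float(np.sum(L2 * M)) / 4.0
    G = L * M
    return f, G


def oblimin_rotate(
    loadings, gamma: float = 0.0, tol: float = 1e-6, max_iter: int = 1000
):
    """Oblique oblimin rotation of a loading matrix.

    Gradient-projection iteration over the rotation matrix; k = 1 is the
    identity operation. Returns (rotated loadings, factor correlations).
    Column signs are fixed so each factor's largest-|loading| entry is
    positive. Raises RuntimeError if the iteration cap is hit.
    """
    L0 = np.asarray(loadings, dtype=float)
    index = loadings.index if isinstance(loadings, pd.DataFrame) else None
    if L0.ndim != 2:
        raise ValueError("loadings must be 2-D")
    k = L0.shape[1]
    if k == 1:
        L, phi = L0.copy(), np.eye(1)
    else:
        L, phi, _, converged = _gpa_oblique(L0, gamma=gamma, tol=tol, max_iter=max_iter)
        if not converged:
            raise RuntimeError(
                f"oblimin rotation did not converge within {max_iter} iterations"
            )
    L, phi = _fix_signs(L, phi)
    if index is not None:
        L = pd.DataFrame(L, index=index, columns=_factor_names(k))
    return L, phi


def _gpa_oblique(
    A: np.ndarray, gamma: float = 0.0, tol: float = 1e-6, max_iter: int = 1000
):
    """Oblique gradient-projection rotation minimising the oblimin criterion.

    Returns (rotated loadings, factor correlation matrix, criterion value,
    converged flag).
    """
    k = A.shape[1]
    T = np.eye(k)
    Ti = np.eye(k)
    L = A.copy()
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = float(np.sqrt(np.sum(Gp**2)))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            v = 1.0 / np.sqrt((X**2).sum(axis=0))
            Tt = X * v
            Ti = np.linalg.inv(Tt)
            Lt = A @ Ti.T
            ft, Gq = _oblimin_criterion(Lt, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, L, f = Tt, Lt, ft
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi, f, converged


# ---------------------------------------------------------------------------
# Confirmatory factor analysis
# ---------------------------------------------------------------------------


@dataclass
class CfaFit:
    """Fitted confirmatory factor-analysis model."""

    structure: dict[str, list[str]]
    loadings: pd.DataFrame  # foods x factors, zero off-structure
    phi: np.ndarray
    uniquenesses: pd.Series
    fit_indices: dict[str, float]
    scores: pd.DataFrame  # regression-method factor scores (zero mean)
    converged: bool
    n: int = 0
    diagnostics: dict = field(default_factory=dict)


def cfa_fit(
    data: pd.DataFrame,
    structure: dict[str, list[str]],
    max_iter: int = 500,
) -> CfaFit:
    """Fit a confirmatory factor model by maximum likelihood.

    Each factor loads only on the foods named in `structure`; factor
    variances are fixed at 1 so loadings are comparable across factors,
    and factor correlations are free (oblique). Minimises the ML
    discrepancy F = log|Sigma| + tr(S Sigma^-1) - log|S| - p on the sample
    covariance. Reports CFI, TLI, RMSEA, SRMR, the discrepancy and a
    chi-square, plus regression-method (Thurstone) factor scores.
    """
    factors = list(structure)
    if not factors:
        raise ValueError("structure must contain at least one factor")
    for fac, foods in structure.items():
        if len(set(foods)) < 2:
            raise ValueError(
                f"factor {fac!r} is empirically underidentified: needs >= 2 "
                f"distinct indicator foods, has {sorted(set(foods))}"
            )
        missing = [f for f in foods if f not in data.columns]
        if missing:
            raise KeyError(f"factor {fac!r} references foods absent from data: {missing}")
    foods = list(dict.fromkeys(f for fac in factors for f in structure[fac]))
    if len(factors) == 1 and len(structure[factors[0]]) < 3:
        raise ValueError(
            f"factor {factors[0]!r} is empirically underidentified: a single "
            "factor needs >= 3 indicators"
        )
    X = data[foods].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("CFA requires complete data")
    n, p = X.shape
    k = len(factors)
    S = np.cov(X, rowvar=False, ddof=1)
    var = np.diag(S)

    membership = [
        (foods.index(f), j) for j, fac in enumerate(factors) for f in dict.fromkeys(structure[fac])
    ]
    rows = np.array([m[0] for m in membership])
    cols = np.array([m[1] for m in membership])
    n_lam = len(membership)
    n_phi = k * (k - 1) // 2
    tri = np.triu_indices(k, 1)

    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular; CFA cannot be fit")

    mult = np.bincount(rows, minlength=p).astype(float)

    def unpack(theta):
        lam = theta[:n_lam]
        psi = np.exp(theta[n_lam : n_lam + p])
        z = theta[n_lam + p :]
        Lam = np.zeros((p, k))
        Lam[rows, cols] = lam
        phi = np.eye(k)
        if n_phi:
            phi[tri] = np.tanh(z)
            phi[(tri[1], tri[0])] = np.tanh(z)
        return Lam, psi, phi

    def obj_grad(theta):
        Lam, psi, phi = unpack(theta)
        Sigma = Lam @ phi @ Lam.T + np.diag(psi)
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        Sinv = np.linalg.inv(Sigma)
        F = logdet + float(np.trace(S @ Sinv)) - logdet_S - p
        A = Sinv - Sinv @ S @ Sinv
        g_lam = 2.0 * (A @ Lam @ phi)[rows, cols]
        g_psi = np.diag(A) * psi  # chain rule through log-parametrisation
        grad = np.concatenate([g_lam, g_psi])
        if n_phi:
            Gphi = Lam.T @ A @ Lam
            z = theta[n_lam + p :]
            g_z = 2.0 * Gphi[tri] * (1.0 - np.tanh(z) ** 2)
            grad = np.concatenate([grad, g_z])
        return F, grad

    theta0 = np.concatenate(
        [
            np.sqrt(0.5 * var[rows] / mult[rows]),
            np.log(0.5 * var),
            np.zeros(n_phi),
        ]
    )
    res = optimize.minimize(
        obj_grad, theta0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter}
    )
    Lam, psi, phi = unpack(res.x)
    Lam, phi = _fix_signs(Lam, phi)
    F = float(res.fun)

    # fit indices against the independence baseline
    n_free = n_lam + p + n_phi
    df_model = p * (p + 1) // 2 - n_free
    chi2 = max((n - 1) * F, 0.0)
    F_base = float(np.sum(np.log(var))) - logdet_S
    chi2_b = max((n - 1) * F_base, 0.0)
    df_b = p * (p - 1) // 2
    denom = max(chi2_b - df_b, chi2 - df_model, 0.0)
    cfi = 1.0 - (max(chi2 - df_model, 0.0) / denom if denom > 0 else 0.0)
    if df_b > 0 and df_model > 0 and chi2_b / df_b > 1.0:
        tli = ((chi2_b / df_b) - (chi2 / df_model)) / ((chi2_b / df_b) - 1.0)
    else:
        tli = 1.0
    rmsea = (
        float(np.sqrt(max(chi2 - df_model, 0.0) / (df_model * (n - 1))))
        if df_model > 0
        else 0.0
    )
    Sigma = Lam @ phi @ Lam.T + np.diag(psi)
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    srmr = float(np.sqrt(np.mean(resid[np.tril_indices(p)] ** 2)))
    fit_indices = {
        "cfi": float(cfi),
        "tli": float(tli),
        "rmsea": rmsea,
        "srmr": srmr,
        "discrepancy": F,
        "chi2": float(chi2),
        "df": float(df_model),
    }

    # regression-method factor scores: (X - mean) Sigma^-1 Lambda Phi
    B = np.linalg.solve(Sigma, Lam @ phi)
    scores = (X - X.mean(axis=0)) @ B
    ids = data.index
    return CfaFit(
        structure={f: list(structure[f]) for f in factors},
        loadings=pd.DataFrame(Lam, index=foods, columns=factors),
        phi=phi,
        uniquenesses=pd.Series(psi, index=foods),
        fit_indices=fit_indices,
        scores=pd.DataFrame(scores, index=ids, columns=factors),
        converged=bool(res.success),
        n=n,
        diagnostics={"nit": int(res.nit), "message": str(res.message)},
    )
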