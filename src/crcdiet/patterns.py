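"""Data-driven dietary patterns via repeated half-split exploratory /
confirmatory factor analysis.

For each of `n_rep` random half-splits of the participants, exploratory
factor analysis (ML + oblimin) is run on one half for every factor count
in `k_range`; the foods loading above `loading_thresh` define a
confirmatory structure fitted on the other half. Confirmatory fitness is
summarised per factor count; the factor counts whose averaged fitness sits
within a tolerance of the best form the plateau, and factors appearing in
the plateau solutions are matched across splits (and across factor counts)
by Tucker congruence. Constructs reproduced in every split become the
stable pattern set, and one final confirmatory fit on all participants
yields the participant pattern scores used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factor import CfaFit, HeywoodWarning, cfa_fit, efa_ml, tucker_phi

DEFAULT_K_RANGE = range(2, 19)  # candidate factor counts
DEFAULT_N_REP = 5  # random half-splits
DEFAULT_LOADING_THRESH = 0.3  # food joins a factor when |loading| exceeds this
DEFAULT_PHI_THRESH = 0.85  # Tucker congruence counting as "the same" construct
DEFAULT_PLATEAU_TOL = 0.02  # combined-fitness tolerance defining the plateau


@dataclass
class Pattern:
    """One stable data-driven dietary pattern."""

    name: str
    foods: list[str]
    loadings: pd.Series  # signed loadings over the full food space (final CFA)
    n_splits_found: int  # splits in which a congruent factor appeared
    n_occurrences: int  # (split, k) solutions containing a congruent factor


@dataclass
class PatternSet:
    """Stable patterns plus final-CFA participant scores and diagnostics."""

    patterns: list[Pattern]
    scores: pd.DataFrame | None  # participants x patterns, zero mean
    final_fit: CfaFit | None
    fitness_table: pd.DataFrame  # per-k averaged CFA fit indices
    plateau: list[int]
    settings: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.patterns


@dataclass
class _Candidate:
    rep: int
    k: int
    vector: np.ndarray  # CFA loading vector over the full food space
    fitness: float


def _combined_fitness(fit_indices: dict[str, float]) -> float:
    """Scalar CFA fitness: mean of CFI, TLI, 1-RMSEA, 1-SRMR (higher better)."""
    return float(
        np.mean(
            [
                fit_indices["cfi"],
                fit_indices["tli"],
                1.0 - fit_indices["rmsea"],
                1.0 - fit_indices["srmr"],
            ]
        )
    )


def _structure_from_loadings(
    loadings: pd.DataFrame, thresh: float
) -> dict[str, list[str]]:
    """Foods with |loading| > thresh per factor; factors with < 2 foods drop."""
    structure = {}
    for j, col in enumerate(loadings.columns):
        foods = list(loadings.index[np.abs(loadings[col]) > thresh])
        if len(foods) >= 2:
            structure[f"F{j + 1}"] = foods
    return structure


def stability_select(
    data: pd.DataFrame,
    k_range=DEFAULT_K_RANGE,
    n_rep: int = DEFAULT_N_REP,
    loading_thresh: float = DEFAULT_LOADING_THRESH,
    seed: int | None = None,
    phi_thresh: float = DEFAULT_PHI_THRESH,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
) -> PatternSet:
    """Derive cross-split-stable dietary patterns from a food matrix.

    `data` is participants x foods (frequency levels; any complete numeric
    matrix works). Returns a PatternSet; when nothing reproduces across all
    splits the result is an explicit empty set, not an exception.
    """
    ks = [int(k) for k in k_range]
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    if data.isna().to_numpy().any():
        raise ValueError("pattern derivation requires complete data")
    foods = list(data.columns)
    n = len(data)
    rng = np.random.default_rng(seed)

    candidates: list[_Candidate] = []
    fit_rows = []
    for rep in range(n_rep):
        perm = rng.permutation(n)
        half1 = data.iloc[np.sort(perm[: n // 2])]
        half2 = data.iloc[np.sort(perm[n // 2 :])]
        for k in ks:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", HeywoodWarning)
                    efa = efa_ml(half1, k)
            except (ValueError, RuntimeError):
                continue
            structure = _structure_from_loadings(efa.loadings, loading_thresh)
            if not structure:
                continue
            try:
                cfa = cfa_fit(half2, structure)
            except (ValueError, KeyError, np.linalg.LinAlgError):
                continue
            fitness = _combined_fitness(cfa.fit_indices)
            fit_rows.append(
                {"rep": rep, "k": k, "fitness": fitness, **cfa.fit_indices}
            )
            for fac in cfa.loadings.columns:
                vec = cfa.loadings[fac].reindex(foods).fillna(0.0).to_numpy()
                if np.any(vec != 0):
                    candidates.append(_Candidate(rep, k, vec, fitness))

    settings = {
        "k_range": ks,
        "n_rep": n_rep,
        "loading_thresh": loading_thresh,
        "phi_thresh": phi_thresh,
        "plateau_tol": plateau_tol,
    }
    fit_table = pd.DataFrame(fit_rows)
    if fit_table.empty:
        return PatternSet([], None, None, fit_table, [], settings)

    per_k = fit_table.groupby("k")[["fitness", "cfi", "tli", "rmsea", "srmr"]].mean()
    plateau = list(per_k.index[per_k["fitness"] >= per_k["fitness"].max() - plateau_tol])
    pool = [c for c in candidates if c.k in plateau]

    # dedupe within each split (across k), best fitness first
    per_rep: dict[int, list[_Candidate]] = {}
    for cand in sorted(pool, key=lambda c: -c.fitness):
        reps = per_rep.setdefault(cand.rep, [])
        if all(abs(tucker_phi(cand.vector, c.vector)) < phi_thresh for c in reps):
            reps.append(cand)

    # constructs present (|phi| >= thresh) in every split are stable
    refs = per_rep.get(0, [])
    stable: list[tuple[_Candidate, int, int]] = []
    for ref in refs:
        found_in = {0}
        occurrences = sum(
            1 for c in pool if abs(tucker_phi(ref.vector, c.vector)) >= phi_thresh
        )
        best = ref
        for rep_id, cands in per_rep.items():
            if rep_id == 0:
                continue
            matches = [
                c for c in cands if abs(tucker_phi(ref.vector, c.vector)) >= phi_thresh
            ]
            if matches:
                found_in.add(rep_id)
                top = max(matches, key=lambda c: c.fitness)
                if top.fitness > best.fitness:
                    best = top
        if len(found_in) == n_rep:
            stable.append((best, len(found_in), occurrences))

    if not stable:
        return PatternSet([], None, None, per_k.reset_index(), plateau, settings)

    structure = {}
    meta = {}
    for i, (cand, n_found, n_occ) in enumerate(stable):
        name = f"pattern_{i + 1:02d}"
        support = [foods[j] for j in np.flatnonzero(cand.vector)]
        structure[name] = support
        meta[name] = (n_found, n_occ)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HeywoodWarning)
            final = cfa_fit(data, structure)
    except (ValueError, np.linalg.LinAlgError):
        final = None

    patterns = []
    for name, support in structure.items():
        if final is not None:
            load = final.loadings[name].reindex(foods).fillna(0.0)
        else:
            idx = list(structure).index(name)
            load = pd.Series(stable[idx][0].vector, index=foods)
        patterns.append(
            Pattern(
                name=name,
                foods=support,
                loadings=load,
                n_splits_found=meta[name][0],
                n_occurrences=meta[name][1],
            )
        )
    scores = extract_scores(final) if final is not None else None
    return PatternSet(patterns, scores, final, per_k.reset_index(), plateau, settings)


def extract_scores(final_fit: CfaFit) -> pd.DataFrame:
    """Participant x pattern score table from the final confirmatory fit.

    Scores are regression-method factor scores and have exactly zero mean.
    """
    if final_fit is None:
        raise ValueError("no final CFA fit available")
    return final_fit.scores.copy()
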