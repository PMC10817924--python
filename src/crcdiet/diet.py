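"""FFQ preparation: frequency mapping, energy-density adjustment, a priori
components, and the 3-level alcohol covariate.

Food-frequency questionnaires record each food on a 9-level ordinal scale
from "never" up to ">= 4 times per day". Analyses work on derived
quantities: frequencies per day, amounts expressed per 1000 kcal of total
energy (the energy-density method), hypothesis-driven component amounts
(sums of constituent foods), and a categorical alcohol confounder with a
separate level for non-consumers.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Frequency-per-day value for each of the 9 ordinal FFQ levels. The scale
#: endpoints are fixed ("never" -> 0/day, ">= 4 times per day" -> 4/day);
#: interior levels follow common FFQ conventions (0.5/month, 1-3/month,
#: 1/week, 2-3/week, 4-6/week, 1/day, 2-3/day) and are configurable by
#: passing an alternative mapping to :func:`map_frequency_levels`.
DEFAULT_FREQUENCY_MAP: dict[int, float] = {
    1: 0.0,
    2: 0.5 / 30.0,
    3: 2.0 / 30.0,
    4: 1.0 / 7.0,
    5: 2.5 / 7.0,
    6: 5.0 / 7.0,
    7: 1.0,
    8: 2.5,
    9: 4.0,
}


def map_frequency_levels(levels, mapping: Mapping[int, float] | None = None):
    """Map ordinal FFQ levels (1-9) to intake frequencies per day.

    Parameters
    ----------
    levels : array-like of int
        Ordinal levels on the 9-level scale.
    mapping : dict, optional
        Level -> frequency/day. Must be monotone non-decreasing with
        mapping[1] == 0. Defaults to :data:`DEFAULT_FREQUENCY_MAP`.

    Returns
    -------
    numpy.ndarray or pandas object of float frequencies per day.
    """
    if mapping is None:
        mapping = DEFAULT_FREQUENCY_MAP
    vals = np.asarray(levels)
    if not np.issubdtype(vals.dtype, np.integer):
        if np.issubdtype(vals.dtype, np.floating) and np.all(
            np.mod(vals[~np.isnan(vals.astype(float))], 1) == 0
        ):
            vals = vals.astype(int)
        else:
            raise ValueError("frequency levels must be integers on the 1-9 scale")
    if vals.size and (vals.min() < 1 or vals.max() > 9):
        bad = vals[(vals < 1) | (vals > 9)]
        raise ValueError(f"frequency levels out of range 1-9: {np.unique(bad)}")
    lut = np.array([mapping[i] for i in range(1, 10)], dtype=float)
    if np.any(np.diff(lut) < 0):
        raise ValueError("frequency mapping must be monotone non-decreasing")
    out = lut[vals - 1]
    if isinstance(levels, pd.DataFrame):
        return pd.DataFrame(out, index=levels.index, columns=levels.columns)
    if isinstance(levels, pd.Series):
        return pd.Series(out, index=levels.index, name=levels.name)
    return out


def energy_adjust(intake, energy, per_kcal: float = 1000.0):
    """Energy-density adjustment: intake per `per_kcal` kcal of total energy.

    density = intake / energy * per_kcal. Linear in intake and invariant to
    jointly scaling intake and energy.
    """
    intake_arr = np.asarray(intake, dtype=float)
    energy_arr = np.asarray(energy, dtype=float)
    if np.any(energy_arr <= 0):
        raise ValueError("total energy must be > 0 for energy-density adjustment")
    if intake_arr.ndim == 2 and energy_arr.ndim == 1:
        energy_arr = energy_arr[:, None]
    out = intake_arr / energy_arr * per_kcal
    if isinstance(intake, pd.DataFrame):
        return pd.DataFrame(out, index=intake.index, columns=intake.columns)
    if isinstance(intake, pd.Series):
        return pd.Series(out, index=intake.index, name=intake.name)
    return out


def build_apriori_components(
    amounts: pd.DataFrame, defs: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Sum constituent food amounts into hypothesis-driven components.

    `amounts` is participants x foods (g/day or mg/day); `defs` maps a
    component name to the list of constituent food columns. Each component
    is the plain sum of its constituents; a food appearing in a definition
    list twice is counted once.
    """
    out = {}
    for name, foods in defs.items():
        foods = list(dict.fromkeys(foods))  # dedupe, keep order
        missing = [f for f in foods if f not in amounts.columns]
        if missing:
            raise KeyError(
                f"component {name!r} references unknown foods: {missing}"
            )
        out[name] = amounts[foods].sum(axis=1)
    return pd.DataFrame(out, index=amounts.index)


def load_component_defs(path) -> dict[str, list[str]]:
    """Read component definitions from a YAML file (name -> list of foods)."""
    with open(path, "r", encoding="utf-8") as fh:
        defs = yaml.safe_load(fh)
    if not isinstance(defs, dict):
        raise ValueError("component definitions must be a mapping")
    return {str(k): [str(f) for f in v] for k, v in defs.items()}


def categorize_alcohol(
    intake: pd.Series, sex: pd.Series, tie: str = "below"
) -> pd.Series:
    """3-level alcohol category: zero intake, or below/above the
    sex-specific median of the non-zero intakes.

    Values exactly at the median go to "below" by default (`tie="below"`);
    set `tie="above"` for the opposite convention.

    Raises
    ------
    ValueError
        If intakes are negative or a sex stratum has no non-zero intakes.
    """
    intake = pd.Series(intake).astype(float)
    sex = pd.Series(sex)
    if np.any(intake.to_numpy() < 0):
        raise ValueError("alcohol intakes must be non-negative")
    if tie not in ("below", "above"):
        raise ValueError("tie must be 'below' or 'above'")
    out = pd.Series(index=intake.index, dtype=object)
    for s, idx in intake.groupby(sex).groups.items():
        vals = intake.loc[idx]
        nonzero = vals[vals > 0]
        if nonzero.empty:
            raise ValueError(f"sex stratum {s!r} has no non-zero alcohol intakes")
        med = float(nonzero.median())
        cat = np.where(
            vals == 0,
            "zero",
            np.where(
                (vals <= med) if tie == "below" else (vals < med), "below", "above"
            ),
        )
        out.loc[idx] = cat
    return out
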