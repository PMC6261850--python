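"""Prevalence-based (Sullivan) expectancies and the incidence-based comparison.

Sullivan's method weights the life-table person-years schedule by the
age-specific prevalence of a state:

    e_j(x) = (1 / l_x) * sum_{k = x}^{99} L_k d_j(k),

where d_j(k) is the proportion of alive persons in state j at age k. It uses
no transition information: when transition rates change quickly, prevalences
— which carry the history of earlier years — lag behind, and Sullivan
expectancies can miss both levels and trends that an incidence-based
multistate (Markov) life table picks up immediately. Under a time-stationary
regime whose mortality matches the life table, the two coincide.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import StateExpectancySet
from .mortality import ReferenceLifeTable
from .probability import TransitionProbabilitySet
from .states import (
    MAX_AGE,
    MIN_AGE,
    N_ALIVE,
    STATE_FROM_LABEL,
    State,
)

__all__ = [
    "PrevalenceSchedule",
    "prevalence_schedule",
    "cohort_prevalence",
    "sullivan_expectancy",
    "awle",
    "ComparisonTable",
    "compare_markov_sullivan",
]


@dataclass
class PrevalenceSchedule:
    """d[age, state]: share of alive persons in each state at each age."""

    d: np.ndarray  # (n_age, 4)
    ages: np.ndarray
    exposure: np.ndarray | None = None
    sex: str = ""
    occupation: str = ""
    period: object = None

    def state_prevalence(self, state: State | str) -> np.ndarray:
        if isinstance(state, str):
            state = STATE_FROM_LABEL[state]
        return self.d[:, int(state)]

    def combined(self, states: Iterable[State | str]) -> np.ndarray:
        """Pooled prevalence of several states (e.g. the labor force E + U)."""
        out = np.zeros(len(self.d))
        for s in states:
            out += self.state_prevalence(s)
        return out


def prevalence_schedule(
    person_years: pd.DataFrame,
    sex: str | None = None,
    occupation: str | None = None,
    period: int | Iterable[int] | None = None,
    ages: np.ndarray | None = None,
) -> PrevalenceSchedule:
    """Raw age-specific state proportions from annual person-year records.

    ``period`` is a calendar year or an iterable of years to pool. Ages with
    zero exposure are linearly interpolated per state from the neighboring
    observed ages (endpoint gaps carry the nearest observed value) and the
    interpolated rows renormalised to sum to one.
    """
    df = person_years
    if sex is not None:
        df = df[df["sex"] == sex]
    if occupation is not None:
        df = df[df["occupation"] == occupation]
    if period is not None:
        years = [period] if np.isscalar(period) else list(period)
        df = df[df["year"].isin(years)]
    if len(df) == 0:
        raise ValueError("no person-years with exposure in the requested stratum-period")
    if ages is None:
        ages = np.arange(MIN_AGE, MAX_AGE + 1)

    counts = np.zeros((len(ages), N_ALIVE))
    tab = df.groupby(["age", "state"]).size()
    for (age, state), cnt in tab.items():
        idx = int(age) - int(ages[0])
        if 0 <= idx < len(ages):
            counts[idx, int(STATE_FROM_LABEL[state])] = cnt
    exposure = counts.sum(axis=1)
    observed = exposure > 0
    if not observed.any():
        raise ValueError("no exposure at any age on the requested grid")

    d = np.zeros_like(counts)
    d[observed] = counts[observed] / exposure[observed, None]
    if (~observed).any():
        obs_idx = np.flatnonzero(observed)
        for j in range(N_ALIVE):
            d[~observed, j] = np.interp(
                np.flatnonzero(~observed), obs_idx, d[observed, j]
            )
        d[~observed] /= d[~observed].sum(axis=1, keepdims=True)
    return PrevalenceSchedule(
        d=d, ages=np.asarray(ages), exposure=exposure, sex=sex or "", occupation=occupation or "", period=period
    )


def cohort_prevalence(
    pset: TransitionProbabilitySet,
    sex: str,
    occupation: str = "all",
    year: int | None = None,
    init_distribution: np.ndarray | None = None,
) -> PrevalenceSchedule:
    """Model-implied cross-sectional prevalence at one calendar year.

    The cohort aged ``a`` in ``year`` entered at age 15 in ``year - (a - 15)``
    and experienced each intervening year's transition probabilities (years
    outside the covered window are clamped to its edges). This is the
    deterministic limit of a simulated population cross-section and makes the
    prevalence lag behind regime shocks exactly as observed data would.
    """
    if year is None:
        raise ValueError("a calendar year is required")
    ages = pset.ages
    d = np.zeros((len(ages), N_ALIVE))
    y0, y1 = pset.years[0], pset.years[-1]
    for ai, age in enumerate(ages):
        birth_cohort_entry = int(year) - (int(age) - MIN_AGE)
        pi = np.zeros(N_ALIVE)
        pi[int(State.INACTIVE)] = 1.0
        for k in range(ai):
            yk = min(max(birth_cohort_entry + k, y0), y1)
            pi = pi @ pset.p[
                pset.sex_index(sex), pset.occ_index(occupation), pset.year_index(yk), k, :, :N_ALIVE
            ]
        alive = pi.sum()
        d[ai] = pi / alive if alive > 0 else np.eye(N_ALIVE)[int(State.RETIRED)]
    return PrevalenceSchedule(d=d, ages=ages, sex=sex, occupation=occupation, period=year)


def sullivan_expectancy(
    reference_lifetable: ReferenceLifeTable,
    prevalence: PrevalenceSchedule | np.ndarray,
    state: State | str | Iterable[State | str] = State.EMPLOYED,
    start_age: int = MIN_AGE,
) -> float:
    """Prevalence-weighted remaining expectancy in a state (years).

    ``state`` may also be a collection of states, whose prevalences are
    pooled (the labor-force participation variant uses employed+unemployed),
    or ``prevalence`` a bare array d(k) on the table's age grid.
    """
    lt = reference_lifetable
    sl = lt.age_slice(start_age)
    l0 = lt.lx[sl.start]
    if l0 == 0:
        raise ValueError(f"no survivors at start age {start_age}")
    if isinstance(prevalence, PrevalenceSchedule):
        if len(prevalence.ages) != len(lt.ages) or prevalence.ages[0] != lt.ages[0]:
            raise ValueError("prevalence and life table are on different age grids")
        if isinstance(state, (State, str)):
            d = prevalence.state_prevalence(state)
        else:
            d = prevalence.combined(state)
    else:
        d = np.asarray(prevalence, dtype=float)
        if len(d) != len(lt.ages):
            raise ValueError("prevalence array does not match the life-table age grid")
    return float((lt.Lx[sl] * d[sl]).sum() / l0)


def awle(expectancies: StateExpectancySet | Mapping[str, float]) -> float:
    """Active working life expectancy: employed plus unemployed years."""
    if isinstance(expectancies, StateExpectancySet):
        return expectancies[State.EMPLOYED] + expectancies[State.UNEMPLOYED]
    return float(expectancies["employed"]) + float(expectancies["unemployed"])


@dataclass
class ComparisonTable:
    """Markov vs Sullivan levels by period plus between-period trends."""

    levels: pd.DataFrame  # period, markov, sullivan, difference
    trends: pd.DataFrame  # period pair, markov_change, sullivan_change

    def __str__(self) -> str:
        return (
            "Levels (years):\n"
            + self.levels.to_string(index=False, float_format=lambda v: f"{v:8.2f}")
            + "\n\nBetween-period changes (years):\n"
            + self.trends.to_string(index=False, float_format=lambda v: f"{v:8.2f}")
        )


def compare_markov_sullivan(
    markov_by_period: Mapping[int, float],
    sullivan_by_period: Mapping[int, float],
) -> ComparisonTable:
    """Head-to-head comparison of the two estimators over common periods."""
    periods = sorted(set(markov_by_period) & set(sullivan_by_period))
    if not periods:
        raise ValueError("no overlapping periods between the two series")
    mk = np.array([markov_by_period[p] for p in periods], dtype=float)
    sv = np.array([sullivan_by_period[p] for p in periods], dtype=float)
    levels = pd.DataFrame(
        {"period": periods, "markov": mk, "sullivan": sv, "difference": mk - sv}
    )
    if len(periods) > 1:
        trends = pd.DataFrame(
            {
                "from_period": periods[:-1],
                "to_period": periods[1:],
                "markov_change": np.diff(mk),
                "sullivan_change": np.diff(sv),
                "trend_difference": np.diff(mk) - np.diff(sv),
            }
        )
    else:
        trends = pd.DataFrame(
            columns=["from_period", "to_period", "markov_change", "sullivan_change", "trend_difference"]
        )
    return ComparisonTable(levels=levels, trends=trends)
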