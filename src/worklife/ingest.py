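"""From spell-level register records to annual states and transition records.

The annual state of a person-year is the state in which the person spent the
most months of the year (ties broken in favor of the economically more active
state). Unemployed and inactive individuals aged 65+ are counted as retired
(no unemployment-benefit entitlement at retirement ages), and everyone aged
80+ is counted as retired. Absence from the register below age 65 means
inactivity; a person who disappears with a recorded death date contributes a
transition to death. The occupational category carried by a person-year is
the highest ever attained up to that year under the total order
skilled non-manual > skilled manual > unskilled non-manual > unskilled manual.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .states import (
    FORCED_RETIRED_AGE,
    MAX_AGE,
    MIN_AGE,
    MISSING_OCC,
    OCCUPATION_RANK,
    OCCUPATIONS,
    RETIREMENT_RECODE_AGE,
    STATE_FROM_LABEL,
    STATE_LABELS,
    TIE_BREAK_ORDER,
    State,
)

PERSON_YEAR_COLUMNS = ["person_id", "sex", "year", "age", "state", "occupation"]
TRANSITION_COLUMNS = ["person_id", "sex", "year", "age", "occupation", "origin", "destination"]

_TIE_PRIORITY = {state: rank for rank, state in enumerate(TIE_BREAK_ORDER)}


def _recode_for_age(state: State, age: int) -> State:
    if age >= FORCED_RETIRED_AGE:
        return State.RETIRED
    if age >= RETIREMENT_RECODE_AGE and state in (State.UNEMPLOYED, State.INACTIVE):
        return State.RETIRED
    return state


def assign_annual_state(spells: Mapping[State | str, int], age: int) -> State:
    """Annual state from the within-year spell durations of one person-year.

    Parameters
    ----------
    spells : mapping of state (``State`` or label) to months in that state.
        An empty mapping means the person was absent from the register, which
        is read as inactivity (or retirement, by the age recodes).
    age : age in years at that calendar year.
    """
    total = 0
    best: State | None = None
    best_key: tuple[int, int] | None = None
    for raw_state, months in spells.items():
        state = STATE_FROM_LABEL[raw_state] if isinstance(raw_state, str) else State(raw_state)
        if state == State.DEAD:
            raise ValueError("death is not a spell state")
        m = int(months)
        if m <= 0:
            raise ValueError(f"spell duration must be a positive month count, got {months}")
        total += m
        key = (-m, _TIE_PRIORITY[state])
        if best_key is None or key < best_key:
            best, best_key = state, key
    if total > 12:
        raise ValueError(f"months per person-year sum to {total} > 12")
    if best is None:
        best = State.INACTIVE
    return _recode_for_age(best, age)


def highest_occupational_category(history: Iterable[str]) -> str:
    """Highest category ever attained; missing entries ignored.

    Returns the missing sentinel when the history contains no known category.
    """
    best_rank = -1
    best = MISSING_OCC
    for cat in history:
        if cat is None or cat == MISSING_OCC or (isinstance(cat, float) and np.isnan(cat)):
            continue
        if cat not in OCCUPATION_RANK:
            raise ValueError(f"unknown occupational category {cat!r}")
        rank = OCCUPATION_RANK[cat]
        if rank > best_rank:
            best_rank, best = rank, cat
    return best


def build_person_years(
    spells: pd.DataFrame,
    deaths: pd.DataFrame | None = None,
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Annual person-year states from spell records.

    One row per person per year from the person's first observed year to the
    year before death (if a death is recorded) or the end of the window; years
    without any spell are filled by the absence rule. The occupation column
    carries the highest category attained up to that year.
    """
    df = spells.copy()
    if (df["months"] <= 0).any():
        raise ValueError("non-positive spell durations")
    if years is None:
        years = (int(df["year"].min()), int(df["year"].max()))
    y0, y1 = years

    death_year = _death_map(deaths)

    # dominant state per person-year: longest total duration, ties broken by
    # the activity priority
    state_code = df["state"].map(lambda s: int(STATE_FROM_LABEL[s]))
    df = df.assign(_state=state_code)
    grouped = (
        df.groupby(["person_id", "year", "_state"], sort=False)
        .agg(
            months=("months", "sum"),
            sex=("sex", "first"),
            birth_year=("birth_year", "first"),
        )
        .reset_index()
    )
    if (grouped.groupby(["person_id", "year"])["months"].sum() > 12).any():
        raise ValueError("months per person-year exceed 12")
    grouped["_prio"] = grouped["_state"].map(lambda s: _TIE_PRIORITY[State(s)])
    grouped = grouped.sort_values(
        ["person_id", "year", "months", "_prio"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    dominant = grouped.drop_duplicates(["person_id", "year"]).copy()
    dominant["age"] = dominant["year"] - dominant["birth_year"]

    # highest occupational category attained up to each year
    occ_rank = df["occupation"].map(lambda c: OCCUPATION_RANK.get(c, -1) if isinstance(c, str) else -1)
    occ_by_py = (
        df.assign(_rank=occ_rank)
        .groupby(["person_id", "year"], sort=True)["_rank"]
        .max()
        .groupby(level=0)
        .cummax()
    )
    dominant = dominant.merge(
        occ_by_py.rename("_occ_rank").reset_index(), on=["person_id", "year"], how="left"
    )

    # fill years absent from the register (inactivity / retirement by age)
    filled = _fill_absent_years(dominant, death_year, y0, y1)

    age = filled["age"].to_numpy()
    state = filled["_state"].to_numpy()
    state = np.where(age >= FORCED_RETIRED_AGE, int(State.RETIRED), state)
    recode = (age >= RETIREMENT_RECODE_AGE) & np.isin(
        state, [int(State.UNEMPLOYED), int(State.INACTIVE)]
    )
    state = np.where(recode, int(State.RETIRED), state)
    filled["state"] = [STATE_LABELS[State(s)] for s in state]
    rank = filled["_occ_rank"].to_numpy()
    filled["occupation"] = [OCCUPATIONS[r] if r >= 0 else MISSING_OCC for r in rank]

    out = filled[(filled["age"] >= MIN_AGE) & (filled["age"] <= MAX_AGE)]
    return out[PERSON_YEAR_COLUMNS].reset_index(drop=True)


def _death_map(deaths: pd.DataFrame | None) -> dict[int, int]:
    if deaths is None or len(deaths) == 0:
        return {}
    return dict(zip(deaths["person_id"], deaths["death_year"]))


def _fill_absent_years(
    dominant: pd.DataFrame, death_year: dict[int, int], y0: int, y1: int
) -> pd.DataFrame:
    """Extend each person's record to a gap-free year range.

    The range runs from the first observed year to the death year minus one
    (when a death is recorded) or the end of the window. Filled years carry
    the inactive state (recoded to retired at 65+ downstream) and the
    occupation attained so far.
    """
    first = dominant.groupby("person_id")["year"].min()
    persons = first.index.to_numpy()
    start = first.to_numpy()
    end = np.array(
        [death_year.get(p, y1 + 1) - 1 for p in persons], dtype=np.int64
    )
    end = np.minimum(end, y1)
    counts = end - start + 1
    if (counts <= 0).any():
        raise ValueError("death recorded before first observed year")
    pid_full = np.repeat(persons, counts)
    year_full = np.concatenate([np.arange(s, e + 1) for s, e in zip(start, end)])
    full = pd.DataFrame({"person_id": pid_full, "year": year_full})
    meta = dominant.groupby("person_id").agg(sex=("sex", "first"), birth_year=("birth_year", "first"))
    full = full.merge(meta, on="person_id", how="left")
    full = full.merge(
        dominant[["person_id", "year", "_state", "_occ_rank"]],
        on=["person_id", "year"],
        how="left",
    )
    full["age"] = full["year"] - full["birth_year"]
    full["_state"] = full["_state"].fillna(int(State.INACTIVE)).astype(np.int64)
    full["_occ_rank"] = (
        full.sort_values(["person_id", "year"]).groupby("person_id")["_occ_rank"].ffill()
    ).fillna(-1).astype(np.int64)
    return full


def build_transition_records(
    person_years: pd.DataFrame,
    deaths: pd.DataFrame | None = None,
    last_year: int | None = None,
) -> pd.DataFrame:
    """Year-to-year transition records from annual person-year states.

    One record per adjacent pair of years a person is present, with the
    covariates measured at the origin year ``t``: a person present at ``t``
    and absent at ``t + 1`` contributes a transition to death when a death in
    ``t + 1`` is recorded, and to inactivity (retirement from age 65)
    otherwise. No record originates in the final data year, which appears
    only as destination.
    """
    df = person_years.sort_values(["person_id", "year"], kind="stable")
    if df.duplicated(["person_id", "year"]).any():
        raise ValueError("duplicate person-year records")
    if last_year is None:
        last_year = int(df["year"].max())
    death_year = _death_map(deaths)

    pid = df["person_id"].to_numpy()
    year = df["year"].to_numpy()
    age = df["age"].to_numpy()
    state = df["state"].map(lambda s: int(STATE_FROM_LABEL[s])).to_numpy()

    same_person = pid[:-1] == pid[1:]
    adjacent = same_person & (year[1:] == year[:-1] + 1)
    if np.any(same_person & (year[1:] == year[:-1])):
        raise ValueError("duplicate years within a person")

    origin_ok = year[:-1] < last_year
    obs = adjacent & origin_ok
    records = {
        "person_id": pid[:-1][obs],
        "sex": df["sex"].to_numpy()[:-1][obs],
        "year": year[:-1][obs],
        "age": age[:-1][obs],
        "occupation": df["occupation"].to_numpy()[:-1][obs],
        "origin": state[:-1][obs],
        "destination": state[1:][obs],
    }
    frames = [pd.DataFrame(records)]

    # exits: last row of a person, or a gap after row t
    is_last = np.ones(len(df), dtype=bool)
    is_last[:-1] = ~adjacent
    exit_rows = is_last & (year < last_year)
    if exit_rows.any():
        ex = df[exit_rows]
        ex_dest = []
        for p, y, a in zip(ex["person_id"], ex["year"], ex["age"]):
            if death_year.get(p) == y + 1:
                ex_dest.append(int(State.DEAD))
            elif a + 1 >= RETIREMENT_RECODE_AGE:
                ex_dest.append(int(State.RETIRED))
            else:
                ex_dest.append(int(State.INACTIVE))
        frames.append(
            pd.DataFrame(
                {
                    "person_id": ex["person_id"].to_numpy(),
                    "sex": ex["sex"].to_numpy(),
                    "year": ex["year"].to_numpy(),
                    "age": ex["age"].to_numpy(),
                    "occupation": ex["occupation"].to_numpy(),
                    "origin": ex["state"].map(lambda s: int(STATE_FROM_LABEL[s])).to_numpy(),
                    "destination": np.array(ex_dest, dtype=np.int64),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["origin"] = [STATE_LABELS[State(s)] for s in out["origin"]]
    out["destination"] = [STATE_LABELS[State(s)] for s in out["destination"]]
    out = out.sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)
    return out[TRANSITION_COLUMNS]


def ingest_spells(
    spells: pd.DataFrame,
    deaths: pd.DataFrame | None = None,
    years: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full ingestion: spells -> (person-year table, transition records)."""
    person_years = build_person_years(spells, deaths=deaths, years=years)
    last_year = years[1] if years is not None else int(person_years["year"].max())
    transitions = build_transition_records(person_years, deaths=deaths, last_year=last_year)
    return person_years, transitions
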