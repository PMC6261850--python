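"""Simulation of register-style working-life trajectories.

Individuals are followed annually from labor-market entry until death or the
end of the observation window, moving between the four labor-force states
according to a :class:`~worklife.regimes.GroundTruthRegime`. Each simulated
person-year is then expanded into one to three within-year spells whose
dominant-duration state equals the simulated annual state, so that the
ingestion stage's dominant-state rule can be exercised and checked by a
round trip. Ages are integer and period-based: a person aged ``a`` in year
``t`` is aged ``a + 1`` in year ``t + 1``.

Deaths are reported in a separate person-level table (the spell schema has no
death field, mirroring register extracts where the death date is a separate
attribute).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .regimes import GroundTruthRegime
from .states import (
    MAX_AGE,
    MIN_AGE,
    MISSING_OCC,
    N_ALIVE,
    OCCUPATIONS,
    RETIREMENT_RECODE_AGE,
    SEXES,
    STATE_LABELS,
    State,
)

SPELL_COLUMNS = ["person_id", "sex", "birth_year", "year", "state", "months", "occupation"]
DEATH_COLUMNS = ["person_id", "death_year"]


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic register sample.

    ``entry_mode`` controls the population design:

    ``cohort_start``
        everyone enters in the first window year at an age drawn uniformly
        from ``entry_age_range`` (default: a closed age-15 cohort), starting
        inactive (or retired at ages 65+);
    ``stationary``
        entry years are uniform over the window, entry ages uniform over
        ``entry_age_range``, and the initial state is drawn from the regime's
        age-conditional state distribution (the occupancy of the first window
        year, conditional on survival), so cross-sections of the simulated
        population reproduce the regime's stationary age profile.
    """

    n_individuals: int = 10_000
    years: tuple[int, int] = (2004, 2013)
    entry_age_range: tuple[int, int] = (15, 15)
    seed: int = 0
    entry_mode: str = "cohort_start"
    occupation_probs: dict[str, float] = field(
        default_factory=lambda: {
            "unskilled_manual": 0.59,
            "unskilled_nonmanual": 0.24,
            "skilled_manual": 0.11,
            "skilled_nonmanual": 0.06,
        }
    )
    missing_occupation_fraction: float = 0.0
    #: per person-year probability of a random occupational-category change
    #: (0 = category fixed for life, the register-analysis default)
    occupation_mobility_prob: float = 0.0
    #: probability that a person-year is split into multiple spells
    multi_spell_prob: float = 0.5
    female_share: float = 0.5

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.entry_mode not in ("cohort_start", "stationary"):
            raise ValueError(f"unknown entry_mode {self.entry_mode!r}")
        probs = np.array([self.occupation_probs.get(o, 0.0) for o in OCCUPATIONS])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupation proportions sum to {probs.sum()}, not 1")
        if not 0.0 <= self.missing_occupation_fraction <= 1.0:
            raise ValueError("missing-occupation fraction must lie in [0, 1]")
        lo, hi = self.entry_age_range
        if not MIN_AGE <= lo <= hi <= MAX_AGE:
            raise ValueError(f"entry ages must lie within {MIN_AGE}-{MAX_AGE}")
        y0, y1 = self.years
        if y1 <= y0:
            raise ValueError("window must span at least two years")

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        kwargs = dict(raw)
        for key in ("years", "entry_age_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class SimulatedData:
    """Output of a simulation run: spells, deaths, and the ground-truth states."""

    spells: pd.DataFrame
    deaths: pd.DataFrame
    #: true annual states, one row per person-year (person_id, sex, year,
    #: age, state, occupation) — the target of the ingestion round trip
    person_years: pd.DataFrame
    config: SyntheticConfig

    def write(self, spells_path, deaths_path=None) -> None:
        self.spells.to_csv(spells_path, index=False)
        if deaths_path is not None:
            self.deaths.to_csv(deaths_path, index=False)


def _conditional_occupancy(pset, si: int, oi: int, ti: int) -> np.ndarray:
    """State distribution by age conditional on being alive, shape (n_age, 4)."""
    n_age = len(pset.ages)
    pi = np.zeros((n_age, N_ALIVE))
    pi[0, int(State.INACTIVE)] = 1.0
    for k in range(n_age - 1):
        pi[k + 1] = pi[k] @ pset.p[si, oi, ti, k, :, :N_ALIVE]
    alive = pi.sum(axis=1, keepdims=True)
    d = np.divide(pi, alive, out=np.zeros_like(pi), where=alive > 0)
    # past certain-death truncation keep the degenerate retired profile
    d[(alive[:, 0] == 0)] = np.eye(N_ALIVE)[int(State.RETIRED)]
    return d


def simulate_trajectories(regime: GroundTruthRegime, config: SyntheticConfig) -> SimulatedData:
    """Simulate individual trajectories and expand them into spell records.

    Fixed seed implies byte-identical output. Within each person-year the
    dominant state receives 7-12 of the 12 months, so the dominant-duration
    rule always recovers the simulated annual state.
    """
    config.validate()
    pset = regime.pset
    y0, y1 = config.years
    if y0 < pset.years[0] or y1 > pset.years[-1]:
        raise ValueError(
            f"window {config.years} not covered by regime years {pset.years[0]}..{pset.years[-1]}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    sex_idx = (rng.random(n) < config.female_share).astype(np.int64)  # 0 male, 1 female
    occ_probs = np.array([config.occupation_probs.get(o, 0.0) for o in OCCUPATIONS])
    occ_idx = rng.choice(len(OCCUPATIONS), size=n, p=occ_probs)
    occ_missing = rng.random(n) < config.missing_occupation_fraction

    lo, hi = config.entry_age_range
    entry_age = rng.integers(lo, hi + 1, size=n)
    if config.entry_mode == "cohort_start":
        entry_year = np.full(n, y0)
    else:
        entry_year = rng.integers(y0, y1 + 1, size=n)

    state = np.where(entry_age >= RETIREMENT_RECODE_AGE, int(State.RETIRED), int(State.INACTIVE))
    if config.entry_mode == "stationary":
        ti0 = pset.year_index(y0)
        for si in range(len(SEXES)):
            for oi in range(len(OCCUPATIONS)):
                mask = (sex_idx == si) & (occ_idx == oi)
                if not mask.any():
                    continue
                d = _conditional_occupancy(pset, si, oi, ti0)
                rows = d[entry_age[mask] - int(pset.ages[0])]
                u = rng.random(int(mask.sum()))
                state[mask] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)

    alive = np.ones(n, dtype=bool)
    death_year = np.full(n, -1, dtype=np.int64)
    py_person, py_year, py_age, py_state = [], [], [], []

    age0 = int(pset.ages[0])
    for year in range(y0, y1 + 1):
        active = alive & (entry_year <= year)
        idx = np.flatnonzero(active)
        if idx.size:
            age_now = entry_age[idx] + (year - entry_year[idx])
            py_person.append(idx)
            py_year.append(np.full(idx.size, year))
            py_age.append(age_now)
            py_state.append(state[idx].copy())
        if year == y1:
            break
        # transition to year + 1
        rows = pset.p[
            sex_idx[idx],
            occ_idx[idx],
            pset.year_index(year),
            entry_age[idx] + (year - entry_year[idx]) - age0,
            state[idx],
            :,
        ]
        u = rng.random(idx.size)
        dest = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
        died = dest == int(State.DEAD)
        alive[idx[died]] = False
        death_year[idx[died]] = year + 1
        state[idx[~died]] = dest[~died]

    person = np.concatenate(py_person) if py_person else np.array([], dtype=np.int64)
    years_arr = np.concatenate(py_year) if py_year else np.array([], dtype=np.int64)
    ages_arr = np.concatenate(py_age) if py_age else np.array([], dtype=np.int64)
    states_arr = np.concatenate(py_state) if py_state else np.array([], dtype=np.int64)

    occ_of_py = _occupation_per_person_year(
        rng, occ_idx[person], config.occupation_mobility_prob
    )
    occ_labels = np.array(OCCUPATIONS)[occ_of_py]
    occ_labels = np.where(occ_missing[person], MISSING_OCC, occ_labels)

    person_years = pd.DataFrame(
        {
            "person_id": person,
            "sex": np.array(SEXES)[sex_idx[person]],
            "birth_year": years_arr - ages_arr,
            "year": years_arr,
            "age": ages_arr,
            "state": [STATE_LABELS[State(s)] for s in states_arr],
            "occupation": occ_labels,
        }
    )

    spells = _expand_spells(rng, person_years, states_arr, config.multi_spell_prob)
    died_mask = death_year >= 0
    deaths = pd.DataFrame(
        {"person_id": np.flatnonzero(died_mask), "death_year": death_year[died_mask]}
    )
    return SimulatedData(spells=spells, deaths=deaths, person_years=person_years, config=config)


def _occupation_per_person_year(
    rng: np.random.Generator, base_occ: np.ndarray, mobility_prob: float
) -> np.ndarray:
    """Occupation index per person-year; optional random per-year changes."""
    if mobility_prob <= 0.0:
        return base_occ
    occ = base_occ.copy()
    switch = rng.random(occ.size) < mobility_prob
    occ[switch] = rng.integers(0, len(OCCUPATIONS), size=int(switch.sum()))
    return occ


def _expand_spells(
    rng: np.random.Generator,
    person_years: pd.DataFrame,
    states_arr: np.ndarray,
    multi_spell_prob: float,
) -> pd.DataFrame:
    """Expand annual states into 1-3 spells; dominant state keeps >= 7 months."""
    m = len(person_years)
    multi = rng.random(m) < multi_spell_prob
    dom_months = np.where(multi, rng.integers(7, 12, size=m), 12)
    rem = 12 - dom_months

    # filler states: one or two alive states different from the dominant one
    offset1 = rng.integers(1, N_ALIVE, size=m)
    filler1 = (states_arr + offset1) % N_ALIVE
    offset2 = rng.integers(1, N_ALIVE - 1, size=m)
    filler2 = (filler1 + offset2) % N_ALIVE
    filler2 = np.where(filler2 == states_arr, (filler2 + 1) % N_ALIVE, filler2)
    two_fillers = multi & (rem >= 2) & (rng.random(m) < 0.5)
    months2 = np.where(two_fillers, rng.integers(1, np.maximum(rem, 2)), 0)
    months1 = rem - months2

    base = person_years[["person_id", "sex", "birth_year", "year", "occupation"]]
    parts = [
        base.assign(state=person_years["state"].to_numpy(), months=dom_months, _ord=0)
    ]
    for filler, months, order in ((filler1, months1, 1), (filler2, months2, 2)):
        mask = months > 0
        if mask.any():
            parts.append(
                base[mask].assign(
                    state=[STATE_LABELS[State(s)] for s in filler[mask]],
                    months=months[mask],
                    _ord=order,
                )
            )
    spells = pd.concat(parts, ignore_index=True)
    spells = spells.sort_values(["person_id", "year", "_ord"], kind="stable").drop(columns="_ord")
    return spells[SPELL_COLUMNS].reset_index(drop=True)


def write_config(config: SyntheticConfig, path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
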