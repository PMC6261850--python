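"""Ground-truth transition regimes for synthetic register data.

A regime is a fully specified set of annual transition probabilities with
known parameters, used to generate synthetic working-life trajectories and to
serve as the truth in parameter-recovery and consistency tests.

Probabilities are built from additive destination utilities

    u(dest | age, origin, sex, occupation, year)
        = f_dest(age) + gamma[origin, dest] + sex/occupation shifts
          + crisis shift (employment destination, years >= crisis year)

mapped through a softmax over the destinations admissible at that age.  The
age curves give an employment-entry probability that rises to a peak in the
mid-20s, a retirement attraction that switches on sharply after the
configured onset age, and a death utility that is linear in age (Gompertz-like
log-mortality).  Structural rules of the annual state space are imposed as
destination bars rather than post-hoc mass transfers: no unemployed/inactive
destinations from age 64 on (destination ages 65+ are counted as retired),
only retirement or death from age 79 on (destination ages 80+), certain death
at age 99, and no exit from retirement.  Because every admissible log-odds is
additive in age, origin, and the categorical covariates, the regime lies in
the same model class as the estimation stage within each age band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probability import TransitionProbabilitySet
from .states import (
    ALIVE_STATES,
    MAX_AGE,
    MIN_AGE,
    N_ALIVE,
    N_STATES,
    OCCUPATIONS,
    SEXES,
    STATE_LABELS,
    State,
)

__all__ = [
    "RegimeParams",
    "GroundTruthRegime",
    "build_truth_regime",
    "build_segregated_market_scenario",
    "sample_transition_records",
    "allowed_origins",
]


@dataclass
class RegimeParams:
    """Parameters of the generating curves.

    Utilities are on the multinomial-logit scale (log-odds units); the
    inactive destination is the zero baseline.
    """

    years: tuple[int, int] = (2004, 2013)
    #: age at which the employment-entry attraction peaks
    entry_peak_age: float = 26.0
    #: width (years of age) of the quadratic entry curve
    entry_width: float = 16.0
    #: employment utility at the peak age
    entry_level: float = 0.8
    #: probability-scale retention level; mapped to an origin-employed
    #: utility bonus of logit(retention)
    retention: float = 0.90
    #: age at which the retirement attraction crosses its midpoint
    retirement_onset: float = 62.0
    #: saturating amplitude and steepness of the retirement utility
    retirement_amplitude: float = 4.0
    retirement_scale: float = 3.0
    #: Gompertz-like mortality: u_death = log(level) + slope * (age - 15)
    mortality_level: float = 2e-5
    mortality_slope: float = 0.16
    #: first calendar year of the downward employment shock (None = no shock)
    crisis_year: int | None = None
    #: utility drop on the employment destination from the crisis year on
    crisis_magnitude: float = 0.0
    #: additive employment-utility shifts by sex and occupation
    sex_employment_shift: dict[str, float] = field(
        default_factory=lambda: {"male": 0.0, "female": -0.25}
    )
    sex_mortality_shift: dict[str, float] = field(
        default_factory=lambda: {"male": 0.0, "female": -0.45}
    )
    occupation_employment_shift: dict[str, float] = field(
        default_factory=lambda: {
            "unskilled_manual": 0.0,
            "unskilled_nonmanual": 0.10,
            "skilled_manual": 0.05,
            "skilled_nonmanual": 0.30,
        }
    )
    occupation_mortality_shift: dict[str, float] = field(
        default_factory=lambda: {
            "unskilled_manual": 0.0,
            "unskilled_nonmanual": -0.05,
            "skilled_manual": -0.10,
            "skilled_nonmanual": -0.20,
        }
    )
    #: origin-state utility shifts gamma[origin][destination]
    unemployment_level: float = -1.3
    unemployment_rise: float = 0.055
    unemployment_fall: float = 0.0028
    origin_shifts: dict[State, dict[State, float]] = field(
        default_factory=lambda: {
            State.EMPLOYED: {State.UNEMPLOYED: 0.9, State.INACTIVE: -0.8},
            State.UNEMPLOYED: {State.UNEMPLOYED: 1.6, State.EMPLOYED: 0.35},
            State.INACTIVE: {},
            State.RETIRED: {},
        }
    )

    def validate(self) -> None:
        if not 0.0 < self.retention < 1.0:
            raise ValueError(f"retention must be a probability in (0, 1), got {self.retention}")
        if not 0.0 <= self.mortality_level <= 1.0:
            raise ValueError(f"mortality level must lie in [0, 1], got {self.mortality_level}")
        if self.mortality_slope < 0:
            raise ValueError("mortality slope must be non-negative")
        if self.entry_width <= 0:
            raise ValueError("entry width must be positive")
        if self.crisis_magnitude < 0:
            raise ValueError("crisis magnitude must be non-negative")
        y0, y1 = self.years
        if y1 <= y0:
            raise ValueError("year range must contain at least two years")


@dataclass
class GroundTruthRegime:
    """A known-parameter transition regime: probability set plus parameters."""

    pset: TransitionProbabilitySet
    params: RegimeParams | dict

    @property
    def years(self) -> tuple[int, ...]:
        return self.pset.years

    @property
    def transition_years(self) -> tuple[int, ...]:
        return self.pset.years[:-1]


def allowed_destinations(age: int) -> list[State]:
    """Destinations admissible from origin age ``age`` (destination age + 1)."""
    if age >= MAX_AGE:
        return [State.DEAD]
    if age >= 79:  # destination age 80+: retired or dead only
        return [State.RETIRED, State.DEAD]
    if age >= 64:  # destination age 65+: no unemployment benefits / inactivity
        return [State.EMPLOYED, State.RETIRED, State.DEAD]
    return [State.EMPLOYED, State.UNEMPLOYED, State.INACTIVE, State.RETIRED, State.DEAD]


def allowed_origins(age: int) -> list[State]:
    """Alive states that can actually occur at ``age`` under the state-space rules."""
    if age >= 80:
        return [State.RETIRED]
    if age >= 65:
        return [State.EMPLOYED, State.RETIRED]
    return list(ALIVE_STATES)


def _softmax_row(utilities: np.ndarray) -> np.ndarray:
    """Softmax tolerating -inf entries (structurally barred destinations)."""
    m = np.max(utilities)
    if not np.isfinite(m):
        raise ValueError("no admissible destination has finite utility")
    w = np.exp(utilities - m)
    return w / w.sum()


def build_truth_regime(params: RegimeParams | None = None) -> GroundTruthRegime:
    """Construct the ground-truth probability array from the parameter block.

    Every destination row sums to one by construction (softmax); the boundary
    rules are structural bars, not renormalised corrections.
    """
    params = params or RegimeParams()
    params.validate()
    y0, y1 = params.years
    years = tuple(range(y0, y1 + 1))
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    p = np.zeros((len(SEXES), len(OCCUPATIONS), len(years), len(ages), N_ALIVE, N_STATES))

    retention_bonus = float(np.log(params.retention / (1.0 - params.retention)))
    with np.errstate(divide="ignore"):
        log_mort = np.log(params.mortality_level)

    for ai, age in enumerate(ages):
        a = float(age)
        u_emp_age = params.entry_level - ((a - params.entry_peak_age) ** 2) / (
            2.0 * params.entry_width**2
        )
        u_unemp_age = (
            params.unemployment_level
            + params.unemployment_rise * (a - MIN_AGE)
            - params.unemployment_fall * (a - MIN_AGE) ** 2
        )
        u_ret_age = params.retirement_amplitude * np.tanh(
            (a - params.retirement_onset) / params.retirement_scale
        )
        u_dead_age = log_mort + params.mortality_slope * (a - MIN_AGE)
        admissible = allowed_destinations(age)
        for si, sex in enumerate(SEXES):
            for oi, occ in enumerate(OCCUPATIONS):
                base = np.full(N_STATES, -np.inf)
                for dest in admissible:
                    if dest == State.EMPLOYED:
                        base[dest] = (
                            u_emp_age
                            + params.sex_employment_shift[sex]
                            + params.occupation_employment_shift[occ]
                        )
                    elif dest == State.UNEMPLOYED:
                        base[dest] = u_unemp_age
                    elif dest == State.INACTIVE:
                        base[dest] = 0.0
                    elif dest == State.RETIRED:
                        base[dest] = u_ret_age
                    else:  # DEAD
                        base[dest] = (
                            u_dead_age
                            + params.sex_mortality_shift[sex]
                            + params.occupation_mortality_shift[occ]
                        )
                for ti, year in enumerate(years):
                    crisis = (
                        -params.crisis_magnitude
                        if params.crisis_year is not None and year >= params.crisis_year
                        else 0.0
                    )
                    for origin in ALIVE_STATES:
                        u = base.copy()
                        if np.isfinite(u[State.EMPLOYED]):
                            u[State.EMPLOYED] += crisis
                        if origin == State.RETIRED:
                            # retirement is absorbing among alive states
                            u[[State.EMPLOYED, State.UNEMPLOYED, State.INACTIVE]] = -np.inf
                        else:
                            shifts = params.origin_shifts.get(origin, {})
                            for dest, shift in shifts.items():
                                if np.isfinite(u[dest]):
                                    u[dest] += shift
                            if origin == State.EMPLOYED and np.isfinite(u[State.EMPLOYED]):
                                u[State.EMPLOYED] += retention_bonus
                        if age >= MAX_AGE:
                            row = np.zeros(N_STATES)
                            row[State.DEAD] = 1.0
                        else:
                            # RETIRED is admissible with finite utility at all
                            # ages < 99, so the softmax is always well defined
                            row = _softmax_row(u)
                        p[si, oi, ti, ai, int(origin), :] = row

    pset = TransitionProbabilitySet(
        p=p, sexes=SEXES, occupations=OCCUPATIONS, years=years, ages=ages, provenance="ground-truth"
    )
    pset.validate()
    return GroundTruthRegime(pset=pset, params=params)


def build_segregated_market_scenario(
    entry_prob_before: float,
    entry_prob_after: float,
    retention: float,
    years: tuple[int, int] = (2000, 2012),
    shock_year: int = 2008,
    mortality_level: float = 5e-4,
    mortality_slope: float = 0.09,
    retirement_age: int = 65,
) -> GroundTruthRegime:
    """Two-track regime for the incidence-vs-prevalence thought experiment.

    Labor-market entrants join an employment or an unemployment track with the
    given entry probability; each track self-retains at ``retention``, and
    track leavers re-enter the entry lottery. The entry probability switches
    from the before- to the after-value at ``shock_year``.  Everybody retires
    at ``retirement_age``; retirement is absorbing. With ``retention = 0`` the
    tracks refresh completely every year and the chain is memoryless.
    """
    for name, v in [
        ("entry_prob_before", entry_prob_before),
        ("entry_prob_after", entry_prob_after),
        ("retention", retention),
    ]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
    if retention >= 1.0 and mortality_level == 0.0:
        raise ValueError("retention >= 1 with no mortality leaves no absorbing exit")

    y0, y1 = years
    yr = tuple(range(y0, y1 + 1))
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    p = np.zeros((len(SEXES), len(OCCUPATIONS), len(yr), len(ages), N_ALIVE, N_STATES))
    E, U, I, R, D = (int(s) for s in State)

    for ti, year in enumerate(yr):
        entry = entry_prob_before if year < shock_year else entry_prob_after
        for ai, age in enumerate(ages):
            q = min(0.7, mortality_level * np.exp(mortality_slope * (age - MIN_AGE)))
            rows = np.zeros((N_ALIVE, N_STATES))
            if age >= MAX_AGE:
                rows[:, D] = 1.0
            elif age >= retirement_age - 1:  # destination age is in retirement
                rows[:, R] = 1.0 - q
                rows[:, D] = q
            else:
                lottery = np.zeros(N_STATES)
                lottery[E], lottery[U] = entry, 1.0 - entry
                rows[I] = (1.0 - q) * lottery
                rows[E] = (1.0 - q) * (retention * _one_hot(E) + (1 - retention) * lottery)
                rows[U] = (1.0 - q) * (retention * _one_hot(U) + (1 - retention) * lottery)
                rows[R, R] = 1.0 - q
                rows[:, D] = q
            p[:, :, ti, ai, :, :] = rows

    pset = TransitionProbabilitySet(
        p=p, sexes=SEXES, occupations=OCCUPATIONS, years=yr, ages=ages, provenance="ground-truth"
    )
    pset.validate()
    params = {
        "scenario": "segregated_market",
        "entry_prob_before": entry_prob_before,
        "entry_prob_after": entry_prob_after,
        "retention": retention,
        "shock_year": shock_year,
        "retirement_age": retirement_age,
        "mortality_level": mortality_level,
        "mortality_slope": mortality_slope,
    }
    return GroundTruthRegime(pset=pset, params=params)


def _one_hot(idx: int) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[idx] = 1.0
    return v


def sample_transition_records(
    regime: GroundTruthRegime,
    n_per_subsample: int,
    seed: int,
    bands: tuple[tuple[int, int], ...] | None = None,
    occupation_probs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw year-to-year transition records directly from a regime.

    For each sex x age-band subsample, origins are drawn uniformly over the
    (age, admissible origin state) cells of the band and destinations from the
    regime's probabilities — a designed sample that covers every covariate
    cell, used for estimator validation. Ages are capped at 98 since age-99
    transitions are deterministic.
    """
    from .states import ESTIMATION_BANDS

    bands = bands or ESTIMATION_BANDS
    rng = np.random.default_rng(seed)
    pset = regime.pset
    tyears = np.array(regime.transition_years)
    occ_p = (
        np.full(len(pset.occupations), 1.0 / len(pset.occupations))
        if occupation_probs is None
        else np.asarray(occupation_probs, dtype=float)
    )
    frames = []
    for si, sex in enumerate(pset.sexes):
        for lo, hi in bands:
            hi_eff = min(hi, MAX_AGE - 1)
            ages = rng.integers(lo, hi_eff + 1, size=n_per_subsample)
            years = rng.choice(tyears, size=n_per_subsample)
            occs = rng.choice(len(pset.occupations), size=n_per_subsample, p=occ_p)
            origins = np.empty(n_per_subsample, dtype=np.int64)
            for age in np.unique(ages):
                mask = ages == age
                allowed = np.array([int(s) for s in allowed_origins(int(age))])
                origins[mask] = rng.choice(allowed, size=int(mask.sum()))
            rows = pset.p[
                si, occs, years - pset.years[0], ages - int(pset.ages[0]), origins, :
            ]
            u = rng.random(n_per_subsample)
            dest = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
            frames.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "age": ages,
                        "year": years,
                        "occupation": np.array(pset.occupations)[occs],
                        "origin": [STATE_LABELS[State(o)] for o in origins],
                        "destination": [STATE_LABELS[State(d)] for d in dest],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
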