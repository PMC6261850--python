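"""Markov multistate life tables: occupancy, expectancies, decompositions.

A synthetic (period) cohort starts at ``start_age`` with an initial
distribution over the four alive states and is propagated forward with the
age-specific transition matrices of a single stratum-year — the period
interpretation: the calendar-year-``t`` probabilities are applied at every
age. State-specific remaining expectancies count one full year per year of
age occupied in a state (annual dominant-state labels carry no fractional
person-time), so

    e_j(x0) = sum_{x = x0}^{99} pi_j(x),

and the four state expectancies sum to the total remaining life expectancy.
A fundamental-matrix backend of the same quantities serves as an algebraic
cross-check, and a Monte-Carlo path simulator as a stochastic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probability import TransitionProbabilitySet
from .states import (
    ALIVE_STATES,
    DECOMPOSITION_BANDS,
    MAX_AGE,
    N_ALIVE,
    RETIREMENT_RECODE_AGE,
    STATE_FROM_LABEL,
    STATE_LABELS,
    State,
    band_label,
)

__all__ = [
    "OccupancyMatrix",
    "StateExpectancySet",
    "AgeBandDecomposition",
    "state_occupancy",
    "state_expectancies",
    "expectancies_via_fundamental_matrix",
    "decompose_by_age_band",
    "change_decomposition",
    "simulate_state_paths",
    "default_init_distribution",
]


@dataclass
class OccupancyMatrix:
    """pi[age, state]: probability of being alive and in the state at the age."""

    pi: np.ndarray  # (n_age, 4)
    start_age: int
    init_distribution: np.ndarray
    sex: str = ""
    occupation: str = ""
    year: int | None = None

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.start_age + len(self.pi))

    @property
    def survival(self) -> np.ndarray:
        return self.pi.sum(axis=1)

    def conditional_prevalence(self) -> np.ndarray:
        """State distribution conditional on being alive, rows summing to 1."""
        s = self.survival[:, None]
        d = np.divide(self.pi, s, out=np.zeros_like(self.pi), where=s > 0)
        d[(s[:, 0] == 0)] = np.eye(N_ALIVE)[int(State.RETIRED)]
        return d


@dataclass
class StateExpectancySet:
    """Remaining expectancy (years) in each labor-force state plus the total."""

    expectancies: np.ndarray  # (4,), indexed by State
    start_age: int
    sex: str = ""
    occupation: str = ""
    year: int | None = None

    @property
    def total(self) -> float:
        return float(self.expectancies.sum())

    def __getitem__(self, state: State | str) -> float:
        if isinstance(state, str):
            state = STATE_FROM_LABEL[state]
        return float(self.expectancies[int(state)])

    def as_dict(self) -> dict[str, float]:
        out = {STATE_LABELS[s]: float(self.expectancies[int(s)]) for s in ALIVE_STATES}
        out["total"] = self.total
        return out


@dataclass
class AgeBandDecomposition:
    """Additive contribution of age bands to an expectancy or its change."""

    contributions: dict[tuple[int, int], float]
    state: State
    quantity: str = "expectancy"  # or "difference"

    @property
    def total(self) -> float:
        return float(sum(self.contributions.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(
            {band_label(b): v for b, v in self.contributions.items()},
            name=STATE_LABELS[self.state],
        )


def default_init_distribution(start_age: int) -> np.ndarray:
    """All inactive at labor-market entry ages, all retired at 65+."""
    init = np.zeros(N_ALIVE)
    if start_age >= RETIREMENT_RECODE_AGE:
        init[int(State.RETIRED)] = 1.0
    else:
        init[int(State.INACTIVE)] = 1.0
    return init


def _alive_blocks(
    pset: TransitionProbabilitySet, sex: str, occupation: str, year: int, start_age: int
) -> np.ndarray:
    mats = pset.matrices(sex, occupation, year)
    a0 = pset.age_index(start_age)
    return mats[a0:, :, :N_ALIVE]


def state_occupancy(
    pset: TransitionProbabilitySet,
    sex: str,
    occupation: str = "all",
    year: int | None = None,
    start_age: int = 15,
    init_distribution: np.ndarray | None = None,
) -> OccupancyMatrix:
    """Forward propagation pi_{x+1} = pi_x P_x over ages start_age..99."""
    if year is None:
        raise ValueError("a calendar year (period) is required")
    init = (
        default_init_distribution(start_age)
        if init_distribution is None
        else np.asarray(init_distribution, dtype=float)
    )
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial distribution sums to {init.sum()}, not 1")
    blocks = _alive_blocks(pset, sex, occupation, year, start_age)
    n = len(blocks)
    pi = np.zeros((n, N_ALIVE))
    pi[0] = init
    for k in range(n - 1):
        pi[k + 1] = pi[k] @ blocks[k]
    return OccupancyMatrix(
        pi=pi,
        start_age=start_age,
        init_distribution=init,
        sex=sex,
        occupation=occupation,
        year=year,
    )


def state_expectancies(occupancy: OccupancyMatrix) -> StateExpectancySet:
    """Column sums of the occupancy matrix: one full year per occupied age."""
    return StateExpectancySet(
        expectancies=occupancy.pi.sum(axis=0),
        start_age=occupancy.start_age,
        sex=occupancy.sex,
        occupation=occupancy.occupation,
        year=occupancy.year,
    )


def expectancies_via_fundamental_matrix(
    pset: TransitionProbabilitySet,
    sex: str,
    occupation: str = "all",
    year: int | None = None,
    start_age: int = 15,
    init_distribution: np.ndarray | None = None,
) -> StateExpectancySet:
    """Expected visits from the absorbing-chain fundamental matrix N = (I-U)^-1.

    The transient space is (age, state) for ages start_age..99 and the four
    alive states; U is the one-step transient block. Identical to the forward
    propagation up to linear-algebra round-off.
    """
    if year is None:
        raise ValueError("a calendar year (period) is required")
    init = (
        default_init_distribution(start_age)
        if init_distribution is None
        else np.asarray(init_distribution, dtype=float)
    )
    blocks = _alive_blocks(pset, sex, occupation, year, start_age)
    n = len(blocks)
    m = n * N_ALIVE
    U = np.zeros((m, m))
    for k in range(n - 1):
        U[k * N_ALIVE : (k + 1) * N_ALIVE, (k + 1) * N_ALIVE : (k + 2) * N_ALIVE] = blocks[k]
    # from the last age (99) everything is absorbed: the last block row is 0
    ImU = np.eye(m) - U
    v = np.zeros(m)
    v[:N_ALIVE] = init
    try:
        visits = np.linalg.solve(ImU.T, v)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - excluded by the 99 wall
        raise np.linalg.LinAlgError("singular I - U: death at age 99 not enforced") from exc
    e = visits.reshape(n, N_ALIVE).sum(axis=0)
    return StateExpectancySet(
        expectancies=e, start_age=start_age, sex=sex, occupation=occupation, year=year
    )


def _check_bands(bands, start_age: int) -> list[tuple[int, int]]:
    clipped = []
    for lo, hi in bands:
        lo_c, hi_c = max(lo, start_age), min(hi, MAX_AGE)
        if lo_c > hi_c:
            continue
        clipped.append((lo_c, hi_c))
    covered = np.zeros(MAX_AGE - start_age + 1, dtype=int)
    for lo, hi in clipped:
        covered[lo - start_age : hi - start_age + 1] += 1
    if (covered > 1).any():
        raise ValueError("age bands overlap")
    if (covered == 0).any():
        missing = np.flatnonzero(covered == 0) + start_age
        raise ValueError(f"age bands do not cover ages {missing.min()}..{missing.max()}")
    return clipped


def decompose_by_age_band(
    occupancy: OccupancyMatrix,
    state: State | str = State.EMPLOYED,
    bands: tuple[tuple[int, int], ...] = DECOMPOSITION_BANDS,
) -> AgeBandDecomposition:
    """Contribution of each age band to a state expectancy (band sums of pi)."""
    if isinstance(state, str):
        state = STATE_FROM_LABEL[state]
    clipped = _check_bands(bands, occupancy.start_age)
    col = occupancy.pi[:, int(state)]
    contributions = {
        (lo, hi): float(col[lo - occupancy.start_age : hi - occupancy.start_age + 1].sum())
        for lo, hi in clipped
    }
    return AgeBandDecomposition(contributions=contributions, state=state, quantity="expectancy")


def change_decomposition(
    occupancy_period1: OccupancyMatrix,
    occupancy_period2: OccupancyMatrix,
    state: State | str = State.EMPLOYED,
    bands: tuple[tuple[int, int], ...] = DECOMPOSITION_BANDS,
) -> AgeBandDecomposition:
    """Per-band difference of contributions (period 2 minus period 1)."""
    if occupancy_period1.start_age != occupancy_period2.start_age or len(
        occupancy_period1.pi
    ) != len(occupancy_period2.pi):
        raise ValueError("occupancy matrices are on different age grids")
    d1 = decompose_by_age_band(occupancy_period1, state, bands)
    d2 = decompose_by_age_band(occupancy_period2, state, bands)
    contributions = {b: d2.contributions[b] - d1.contributions[b] for b in d1.contributions}
    return AgeBandDecomposition(contributions=contributions, state=d1.state, quantity="difference")


def simulate_state_paths(
    pset: TransitionProbabilitySet,
    sex: str,
    occupation: str = "all",
    year: int | None = None,
    n_paths: int = 100_000,
    seed: int = 0,
    start_age: int = 15,
    init_distribution: np.ndarray | None = None,
) -> np.ndarray:
    """Monte-Carlo years-in-state counts, shape (n_paths, 4).

    Paths follow the same period convention as :func:`state_occupancy`; the
    mean of each column estimates the corresponding e_j.
    """
    if year is None:
        raise ValueError("a calendar year (period) is required")
    rng = np.random.default_rng(seed)
    init = (
        default_init_distribution(start_age)
        if init_distribution is None
        else np.asarray(init_distribution, dtype=float)
    )
    mats = pset.matrices(sex, occupation, year)
    a0 = pset.age_index(start_age)
    cdf = np.cumsum(mats, axis=-1)  # (n_age, 4, 5)

    state = rng.choice(N_ALIVE, size=n_paths, p=init)
    alive = np.ones(n_paths, dtype=bool)
    counts = np.zeros((n_paths, N_ALIVE), dtype=np.int64)
    for k in range(a0, len(pset.ages)):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        counts[idx, state[idx]] += 1
        u = rng.random(idx.size)
        dest = (u[:, None] > cdf[k, state[idx], :]).sum(axis=1)
        died = dest == int(State.DEAD)
        alive[idx[died]] = False
        state[idx[~died]] = dest[~died]
    return counts
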