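"""Labor-force state space, occupational categories, and grid constants.

The annual state space has four alive states plus death. Death is absorbing;
retirement is treated as absorbing among the alive states (no un-retirement).
Ages run from 15 (labor-market entry) to 99, the highest attainable age: every
individual alive at 99 dies during that year.
"""

from __future__ import annotations

from enum import IntEnum


class State(IntEnum):
    """Annual labor-force state; integer values index probability arrays."""

    EMPLOYED = 0
    UNEMPLOYED = 1
    INACTIVE = 2
    RETIRED = 3
    DEAD = 4


ALIVE_STATES: tuple[State, ...] = (
    State.EMPLOYED,
    State.UNEMPLOYED,
    State.INACTIVE,
    State.RETIRED,
)
N_ALIVE = len(ALIVE_STATES)
N_STATES = N_ALIVE + 1  # destinations include DEAD

STATE_LABELS: dict[State, str] = {
    State.EMPLOYED: "employed",
    State.UNEMPLOYED: "unemployed",
    State.INACTIVE: "inactive",
    State.RETIRED: "retired",
    State.DEAD: "dead",
}
STATE_FROM_LABEL: dict[str, State] = {v: k for k, v in STATE_LABELS.items()}

#: Tie-break priority when two annual states have equal duration (rule D1):
#: the economically more active state wins.
TIE_BREAK_ORDER: tuple[State, ...] = (
    State.EMPLOYED,
    State.UNEMPLOYED,
    State.RETIRED,
    State.INACTIVE,
)

SEXES: tuple[str, str] = ("male", "female")

#: Occupational tax-group categories, lowest to highest under the total order
#: used for "highest category ever attained": skill dominates, then
#: non-manual over manual (rule D2).
OCCUPATIONS: tuple[str, ...] = (
    "unskilled_manual",
    "unskilled_nonmanual",
    "skilled_manual",
    "skilled_nonmanual",
)
OCCUPATION_RANK: dict[str, int] = {occ: i for i, occ in enumerate(OCCUPATIONS)}

#: Sentinel for a missing occupational category (empty field in CSV).
MISSING_OCC = ""

MIN_AGE = 15
MAX_AGE = 99  # certain death during this year of age
#: Age from which unemployed/inactive individuals are counted as retired
#: (no unemployment-benefit entitlement at retirement ages).
RETIREMENT_RECODE_AGE = 65
#: Age from which everyone is counted as retired regardless of spells.
FORCED_RETIRED_AGE = 80

#: Estimation subsample age bands (closed intervals on age at t): labor-market
#: entry, prime working ages, retirement transition, retirement, advanced age.
ESTIMATION_BANDS: tuple[tuple[int, int], ...] = (
    (15, 29),
    (30, 54),
    (55, 64),
    (65, 79),
    (80, 99),
)

#: Default age bands for expectancy decompositions (closed intervals).
DECOMPOSITION_BANDS: tuple[tuple[int, int], ...] = (
    (15, 19),
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 99),
)

#: Default study window (calendar years of observed states).
DEFAULT_YEARS = (2004, 2013)


def band_label(band: tuple[int, int]) -> str:
    lo, hi = band
    if lo <= MIN_AGE:
        return f"<={hi}"
    if hi >= MAX_AGE:
        return f">={lo}"
    return f"{lo}-{hi}"


def band_of(age: int, bands: tuple[tuple[int, int], ...] = ESTIMATION_BANDS) -> tuple[int, int]:
    for lo, hi in bands:
        if lo <= age <= hi:
            return (lo, hi)
    raise ValueError(f"age {age} outside all bands {bands}")
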