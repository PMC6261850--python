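"""Transition-probability container shared across the package.

A :class:`TransitionProbabilitySet` holds annual transition probabilities
p[sex, occupation, year, age, origin, destination] on the full grid
sex x occupation x calendar year x age 15-99 x 4 alive origins x 5
destinations (the four alive states plus death). ``year`` indexes the origin
year t of a t -> t+1 transition. Rows over destinations sum to one; death is
absorbing; at age 99 death is certain; at ages 80-98 all non-death mass sits
on the retired state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .states import (
    ALIVE_STATES,
    MAX_AGE,
    MIN_AGE,
    N_ALIVE,
    N_STATES,
    OCCUPATIONS,
    SEXES,
    STATE_FROM_LABEL,
    STATE_LABELS,
    State,
)

ROW_SUM_TOL = 1e-10


@dataclass
class TransitionProbabilitySet:
    """Annual transition probabilities on the full stratification grid.

    Parameters
    ----------
    p : ndarray, shape (n_sex, n_occ, n_year, n_age, 4, 5)
        ``p[s, o, t, a, i, j]`` is the probability of being in destination
        state ``j`` at age ``a+1`` in year ``t+1`` given origin state ``i``
        at age ``a`` in year ``t``.
    sexes, occupations, years : labels for the leading axes. ``occupations``
        is ``("all",)`` for occupation-free sets.
    ages : integer ages covered (default 15..99).
    provenance : one of ``ground-truth``, ``model-based``, ``empirical``,
        ``adjusted`` — how the probabilities were obtained.
    """

    p: np.ndarray
    sexes: tuple[str, ...] = SEXES
    occupations: tuple[str, ...] = OCCUPATIONS
    years: tuple[int, ...] = ()
    ages: np.ndarray = field(default_factory=lambda: np.arange(MIN_AGE, MAX_AGE + 1))
    provenance: str = "ground-truth"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.ages = np.asarray(self.ages)
        expected = (
            len(self.sexes),
            len(self.occupations),
            len(self.years),
            len(self.ages),
            N_ALIVE,
            N_STATES,
        )
        if self.p.shape != expected:
            raise ValueError(f"probability array has shape {self.p.shape}, expected {expected}")

    # -- indexing helpers -------------------------------------------------
    def sex_index(self, sex: str) -> int:
        return self.sexes.index(sex)

    def occ_index(self, occupation: str) -> int:
        return self.occupations.index(occupation)

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not covered (years {self.years[0]}..{self.years[-1]})")

    def age_index(self, age: int) -> int:
        idx = int(age) - int(self.ages[0])
        if not 0 <= idx < len(self.ages):
            raise KeyError(f"age {age} outside grid {self.ages[0]}..{self.ages[-1]}")
        return idx

    def matrices(self, sex: str, occupation: str, year: int) -> np.ndarray:
        """All age-specific transition matrices for one stratum-year.

        Returns an array of shape (n_age, 4, 5).
        """
        try:
            return self.p[self.sex_index(sex), self.occ_index(occupation), self.year_index(year)]
        except ValueError as exc:
            raise KeyError(f"stratum (sex={sex!r}, occupation={occupation!r}) not in set") from exc

    # -- validation and normalization -------------------------------------
    def validate(self, tol: float = ROW_SUM_TOL) -> None:
        """Check row sums, the age-99 death wall, and the 80+ retirement rule."""
        sums = self.p.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=tol, rtol=0.0):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(f"destination rows do not sum to 1 (max deviation {worst:.3e})")
        if np.any(self.p < -tol) or np.any(self.p > 1 + tol):
            raise ValueError("probabilities outside [0, 1]")
        a99 = self.age_index(MAX_AGE)
        if not np.allclose(self.p[..., a99, :, State.DEAD], 1.0, atol=tol):
            raise ValueError("death is not certain at age 99")
        # states at ages 80..99 are retired: transitions from ages 79..98
        # place all non-death mass on RETIRED
        lo = self.age_index(79)
        hi = self.age_index(98)
        alive_non_ret = [s for s in ALIVE_STATES if s != State.RETIRED]
        if np.abs(self.p[..., lo : hi + 1, :, alive_non_ret]).max() > tol:
            raise ValueError("non-retired alive mass at destination ages 80+")

    def enforce_boundaries(self) -> "TransitionProbabilitySet":
        """Force the age-grid boundary rules and renormalize rows.

        Destination ages 80-98 (origin ages 79-97) carry alive mass only on
        RETIRED; at origin age 98 the destination age 99 is likewise retired;
        at origin age 99 death is certain. Row renormalization after the
        transfer is exact because mass is moved, not removed.
        """
        q = self.p.copy()
        alive_non_ret = [int(s) for s in ALIVE_STATES if s != State.RETIRED]
        lo = self.age_index(79)
        hi = self.age_index(98)
        moved = q[..., lo : hi + 1, :, alive_non_ret].sum(axis=-1)
        q[..., lo : hi + 1, :, int(State.RETIRED)] += moved
        q[..., lo : hi + 1, :, alive_non_ret] = 0.0
        a99 = self.age_index(MAX_AGE)
        q[..., a99, :, :] = 0.0
        q[..., a99, :, int(State.DEAD)] = 1.0
        q /= q.sum(axis=-1, keepdims=True)
        return replace(self, p=q)

    # -- serialization -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Long format: sex, occupation, year, age, origin, destination, probability."""
        s, o, t, a, i, j = np.meshgrid(
            np.arange(len(self.sexes)),
            np.arange(len(self.occupations)),
            np.arange(len(self.years)),
            np.arange(len(self.ages)),
            np.arange(N_ALIVE),
            np.arange(N_STATES),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "sex": np.array(self.sexes)[s.ravel()],
                "occupation": np.array(self.occupations)[o.ravel()],
                "year": np.array(self.years)[t.ravel()],
                "age": self.ages[a.ravel()],
                "origin": [STATE_LABELS[State(k)] for k in i.ravel()],
                "destination": [STATE_LABELS[State(k)] for k in j.ravel()],
                "probability": self.p.ravel(),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "model-based") -> "TransitionProbabilitySet":
        sexes = tuple(sorted(df["sex"].unique(), key=SEXES.index))
        occs = tuple(df["occupation"].unique())
        years = tuple(sorted(int(y) for y in df["year"].unique()))
        ages = np.arange(int(df["age"].min()), int(df["age"].max()) + 1)
        p = np.zeros((len(sexes), len(occs), len(years), len(ages), N_ALIVE, N_STATES))
        sidx = df["sex"].map({v: k for k, v in enumerate(sexes)}).to_numpy()
        oidx = df["occupation"].map({v: k for k, v in enumerate(occs)}).to_numpy()
        tidx = df["year"].map({v: k for k, v in enumerate(years)}).to_numpy()
        aidx = df["age"].to_numpy() - ages[0]
        iidx = df["origin"].map(lambda x: int(STATE_FROM_LABEL[x])).to_numpy()
        jidx = df["destination"].map(lambda x: int(STATE_FROM_LABEL[x])).to_numpy()
        p[sidx, oidx, tidx, aidx, iidx, jidx] = df["probability"].to_numpy()
        return cls(p=p, sexes=sexes, occupations=occs, years=years, ages=ages, provenance=provenance)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, provenance: str = "model-based") -> "TransitionProbabilitySet":
        return cls.from_dataframe(pd.read_csv(path), provenance=provenance)


def death_probabilities(pset: TransitionProbabilitySet) -> np.ndarray:
    """State-specific annual death probabilities, shape (sex, occ, year, age, origin)."""
    return pset.p[..., int(State.DEAD)]
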