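"""Reference period life tables and mortality alignment of transition sets.

Register-based transition data understate mortality relative to vital
statistics, so the chain's state-specific death probabilities are rescaled
until its occupancy-weighted aggregate death probability matches an external
HMD-style period life table at every age. The scaling is proportional within
each age and origin state, leaving the conditional-on-survival transition
structure untouched; after alignment the chain's total remaining life
expectancy agrees with the reference table's.

Two expectancy conventions coexist on :class:`ReferenceLifeTable`:

``full_year``
    e_x = sum_{k >= x} l_k / l_x — one full year per year of age survived
    into, the same left-endpoint counting the multistate life table uses;
``person_years``
    e_x = sum_{k >= x} L_k / l_x — the classical person-years form used as
    the survival weight in Sullivan's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import default_init_distribution, state_occupancy
from .probability import TransitionProbabilitySet
from .states import MAX_AGE, MIN_AGE, N_ALIVE, State

logger = logging.getLogger(__name__)

RADIX = 100_000.0

__all__ = [
    "ReferenceLifeTable",
    "read_reference_lifetable",
    "lifetable_from_pset",
    "aggregate_mortality",
    "scale_mortality",
    "AdjustmentResult",
    "adjust_probability_set",
]


@dataclass
class ReferenceLifeTable:
    """Period life table on integer ages (truncated and closed at 99)."""

    ages: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    Lx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        self.Lx = np.asarray(self.Lx, dtype=float)

    @classmethod
    def from_qx(cls, ages, qx, radix: float = RADIX, full_year_L: bool = False) -> "ReferenceLifeTable":
        """Build survivors and person-years from death probabilities.

        ``full_year_L`` sets L_x = l_x (left-endpoint convention, matching
        the chain's year counting); the default is the a_x = 0.5 convention
        L_x = l_x (1 - q_x / 2).
        """
        ages = np.asarray(ages, dtype=int)
        qx = np.asarray(qx, dtype=float).copy()
        qx[-1] = 1.0
        lx = radix * np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
        Lx = lx.copy() if full_year_L else lx * (1.0 - qx / 2.0)
        return cls(ages=ages, qx=qx, lx=lx, Lx=Lx)

    def validate(self, tol: float = 1e-8) -> None:
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be consecutive integers")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("death probabilities outside [0, 1]")
        if np.any(np.diff(self.lx) > tol * self.lx[0]):
            raise ValueError("survivors l_x increase with age")
        if abs(self.qx[-1] - 1.0) > tol:
            raise ValueError("q at the final age must be 1 after truncation")
        if np.any(self.Lx < -tol):
            raise ValueError("negative person-years L_x")
        implied = self.lx[:-1] * (1.0 - self.qx[:-1])
        if np.max(np.abs(implied - self.lx[1:])) > tol * self.lx[0]:
            raise ValueError("l_{x+1} != l_x (1 - q_x)")

    def age_slice(self, start_age: int) -> slice:
        i = int(start_age) - int(self.ages[0])
        if not 0 <= i < len(self.ages):
            raise ValueError(f"start age {start_age} outside table ages")
        return slice(i, len(self.ages))

    def expectancy(self, start_age: int = MIN_AGE, convention: str = "full_year") -> float:
        sl = self.age_slice(start_age)
        l0 = self.lx[sl.start]
        if l0 == 0:
            raise ValueError(f"no survivors at start age {start_age}")
        num = self.lx[sl] if convention == "full_year" else self.Lx[sl]
        return float(num.sum() / l0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx, "lx": self.lx, "Lx": self.Lx})


_COLUMN_ALIASES = {
    "age": "age",
    "x": "age",
    "qx": "qx",
    "q_x": "qx",
    "lx": "lx",
    "l_x": "lx",
    "llx": "Lx",
    "l_x_upper": "Lx",
}


def read_reference_lifetable(path, radix: float = RADIX) -> ReferenceLifeTable:
    """Read an HMD-style period life table from delimited text.

    Requires at least age and q_x columns; missing l_x/L_x are reconstructed
    from q_x (radix 100,000; a_x = 0.5). The table is truncated at age 99 and
    closed there with q = 1; an open final age like ``99+`` or ``110+`` is
    accepted. Rows with non-monotone ages or q outside [0, 1] are rejected
    with their row number.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ValueError(f"cannot parse life table {path}: {exc}") from exc
    cols = {}
    for c in df.columns:
        key = str(c).strip().lower().replace("(", "").replace(")", "")
        if key in ("lx",) and str(c).strip()[0] == "L":
            cols[c] = "Lx"
        elif key in _COLUMN_ALIASES:
            cols[c] = _COLUMN_ALIASES[key]
    df = df.rename(columns=cols)
    if "age" not in df.columns or "qx" not in df.columns:
        raise ValueError(f"life table {path} must provide age and qx columns")

    age = df["age"].astype(str).str.replace("+", "", regex=False).astype(int).to_numpy()
    qx = pd.to_numeric(df["qx"], errors="coerce").to_numpy(dtype=float)
    for i, q in enumerate(qx):
        if not 0.0 <= q <= 1.0 or np.isnan(q):
            raise ValueError(f"row {i}: q_x = {q!r} outside [0, 1]")
    if np.any(np.diff(age) <= 0):
        bad = int(np.flatnonzero(np.diff(age) <= 0)[0]) + 1
        raise ValueError(f"row {bad}: ages not strictly increasing")

    keep = (age >= MIN_AGE) & (age <= MAX_AGE)
    age, qx = age[keep], qx[keep]
    if age[0] != MIN_AGE or np.any(np.diff(age) != 1):
        raise ValueError(f"life table must cover consecutive ages from {MIN_AGE}")
    if age[-1] < MAX_AGE:
        raise ValueError(f"life table must reach age {MAX_AGE}")
    qx = qx.copy()
    qx[-1] = 1.0  # truncation: the 99 age class is closed

    if "lx" in df.columns:
        lx = pd.to_numeric(df["lx"], errors="coerce").to_numpy(dtype=float)[keep]
        implied = lx[:-1] * (1.0 - qx[:-1])
        if np.max(np.abs(implied[:-1] - lx[1:-1])) <= 1e-8 * lx[0]:
            Lx = (
                pd.to_numeric(df["Lx"], errors="coerce").to_numpy(dtype=float)[keep]
                if "Lx" in df.columns
                else lx * (1.0 - qx / 2.0)
            )
            table = ReferenceLifeTable(ages=age, qx=qx, lx=lx, Lx=Lx)
            table.validate(tol=1e-6)
            return table
        logger.warning("l_x inconsistent with q_x; reconstructing from q_x")
    return ReferenceLifeTable.from_qx(age, qx, radix=radix)


def lifetable_from_pset(
    pset: TransitionProbabilitySet,
    sex: str,
    occupation: str = "all",
    year: int | None = None,
    init_distribution: np.ndarray | None = None,
    full_year_L: bool = True,
) -> ReferenceLifeTable:
    """Life table implied by a stratum-year of a transition set.

    Survival comes from the chain's occupancy starting at age 15; the default
    L_x = l_x matches the chain's full-year counting, making the table the
    exact mortality companion for Sullivan-vs-Markov comparisons.
    """
    occ = state_occupancy(pset, sex, occupation, year, MIN_AGE, init_distribution)
    s = occ.survival
    qx = np.ones(len(s))
    qx[:-1] = 1.0 - s[1:] / s[:-1]
    return ReferenceLifeTable.from_qx(occ.ages, qx, full_year_L=full_year_L)


def aggregate_mortality(
    pset: TransitionProbabilitySet,
    sex: str,
    occupation: str = "all",
    year: int | None = None,
    init_distribution: np.ndarray | None = None,
) -> np.ndarray:
    """Occupancy-weighted aggregate death probability by age for one stratum."""
    occ = state_occupancy(pset, sex, occupation, year, MIN_AGE, init_distribution)
    w = occ.conditional_prevalence()
    qd = pset.matrices(sex, occupation, year)[..., int(State.DEAD)]
    return (w * qd).sum(axis=1)


def scale_mortality(pset: TransitionProbabilitySet, factor: float) -> TransitionProbabilitySet:
    """Scale all state-specific death probabilities by a common factor.

    Non-death probabilities are renormalised proportionally; the factor is
    capped where it would push a death probability above 1. The age-99 death
    wall is preserved.
    """
    p = pset.p.copy()
    qd = p[..., int(State.DEAD)]
    qd_new = np.clip(qd * factor, 0.0, 1.0)
    a99 = pset.age_index(MAX_AGE)
    qd_new[..., a99, :] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(qd < 1.0, (1.0 - qd_new) / (1.0 - qd), 0.0)
    p[..., :N_ALIVE] *= ratio[..., None]
    p[..., int(State.DEAD)] = qd_new
    out = TransitionProbabilitySet(
        p=p,
        sexes=pset.sexes,
        occupations=pset.occupations,
        years=pset.years,
        ages=pset.ages,
        provenance=pset.provenance,
    )
    out.validate()
    return out


@dataclass
class AdjustmentResult:
    """Aligned probability set plus the per-age scale-factor report."""

    pset: TransitionProbabilitySet
    report: pd.DataFrame
    converged: bool
    max_gap: float


def adjust_probability_set(
    pset: TransitionProbabilitySet,
    reference: ReferenceLifeTable | dict[str, ReferenceLifeTable],
    init_distribution: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> AdjustmentResult:
    """Align each stratum's aggregate mortality with a reference life table.

    For every (sex, occupation, year) stratum the state-specific death
    probabilities at each age are multiplied by a common factor so that the
    occupancy-weighted aggregate death probability equals the reference q_x;
    non-death destinations are renormalised proportionally. Occupancy weights
    are recomputed from the current probabilities and the procedure iterates
    occupancy -> scale -> occupancy until max |q_hat - q_ref| < tol. Factors
    that would push a death probability above 1 are capped and the remaining
    deficit reported.

    ``reference`` is one table for all strata or a mapping sex -> table.
    """
    refs = reference if isinstance(reference, dict) else {s: reference for s in pset.sexes}
    p = pset.p.copy()
    work = TransitionProbabilitySet(
        p=p,
        sexes=pset.sexes,
        occupations=pset.occupations,
        years=pset.years,
        ages=pset.ages,
        provenance="adjusted",
    )
    rows = []
    overall_converged = True
    overall_gap = 0.0
    for sex in pset.sexes:
        ref = refs[sex]
        sl = ref.age_slice(MIN_AGE)
        q_ref = ref.qx[sl][: len(pset.ages)]
        for occupation in pset.occupations:
            for year in pset.years:
                gap, factors, deficits, converged = _adjust_stratum(
                    work, sex, occupation, year, q_ref, init_distribution, tol, max_iter
                )
                overall_converged &= converged
                overall_gap = max(overall_gap, gap)
                rows.append(
                    pd.DataFrame(
                        {
                            "sex": sex,
                            "occupation": occupation,
                            "year": year,
                            "age": pset.ages,
                            "scale_factor": factors,
                            "capped_deficit": deficits,
                        }
                    )
                )
    report = pd.concat(rows, ignore_index=True)
    if not overall_converged:
        logger.warning(
            "mortality adjustment left a residual gap of %.3e (capped death probabilities)",
            overall_gap,
        )
    work.validate()
    return AdjustmentResult(pset=work, report=report, converged=overall_converged, max_gap=overall_gap)


def _adjust_stratum(work, sex, occupation, year, q_ref, init_distribution, tol, max_iter):
    si = work.sex_index(sex)
    oi = work.occ_index(occupation)
    ti = work.year_index(year)
    n_age = len(work.ages)
    init = (
        default_init_distribution(MIN_AGE)
        if init_distribution is None
        else np.asarray(init_distribution, dtype=float)
    )
    factors = np.ones(n_age)
    deficits = np.zeros(n_age)
    gap = np.inf
    for _ in range(max_iter):
        # forward sweep: adjust each age with occupancy implied by the ages
        # already adjusted, so a second pass only confirms the fixed point
        pi = init.copy()
        gap = 0.0
        for k in range(n_age):
            alive = pi.sum()
            w = pi / alive if alive > 0 else np.eye(N_ALIVE)[int(State.RETIRED)]
            row = work.p[si, oi, ti, k]  # (4, 5), modified in place
            qd = row[:, int(State.DEAD)]
            q_hat = float(w @ qd)
            target = q_ref[k]
            gap = max(gap, abs(q_hat - target))
            if target >= 1.0 or k == n_age - 1:
                row[:, :N_ALIVE] = 0.0
                row[:, int(State.DEAD)] = 1.0
                factors[k] = np.inf if q_hat < 1.0 else 1.0
            elif q_hat <= 0.0:
                if target > 0.0:
                    # no occupancy-weighted mortality to scale: impose the
                    # reference level uniformly across origin states
                    alive_mass = row[:, :N_ALIVE].sum(axis=1)
                    qd_new = np.where(alive_mass > 0.0, target, 1.0)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ratio = np.where(
                            alive_mass > 0.0, (1.0 - qd_new) / alive_mass, 0.0
                        )
                    row[:, :N_ALIVE] *= ratio[:, None]
                    row[:, int(State.DEAD)] = qd_new
                    factors[k] = np.inf
            else:
                f = target / q_hat
                # an origin with no alive mass left stays absorbed; scaling
                # uses the row's actual alive mass to avoid cancellation in
                # 1 - qd when qd is close to 1
                alive_mass = row[:, :N_ALIVE].sum(axis=1)
                qd_new = np.where(
                    alive_mass <= 0.0, 1.0, np.minimum(qd * f, 1.0)
                )
                achieved = float(w @ qd_new)
                deficits[k] = max(0.0, target - achieved)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = np.where(
                        alive_mass > 0.0, (1.0 - qd_new) / alive_mass, 0.0
                    )
                row[:, :N_ALIVE] *= ratio[:, None]
                row[:, int(State.DEAD)] = qd_new
                factors[k] = f
            pi = pi @ row[:, :N_ALIVE]
        if gap < tol:
            break
    # final verification pass
    q_hat_final = aggregate_mortality(work, sex, occupation, year, init_distribution)
    gap = float(np.max(np.abs(q_hat_final - q_ref) - deficits.clip(min=0.0)))
    converged = bool(np.all(np.abs(q_hat_final - q_ref) <= np.maximum(tol, deficits + tol)))
    return gap, factors, deficits, converged
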