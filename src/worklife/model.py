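"""High-level modelling interface: fit once, then query expectancies.

:class:`WorkingLifeModel` wraps the estimation pipeline in the familiar
model/results idiom: the model is constructed from transition records (or
straight from spell records), ``fit()`` estimates the subsample multinomial
models, materialises the transition-probability grid, optionally aligns its
mortality with a reference life table, and returns a
:class:`WorkingLifeResults` carrying everything needed for working-life
expectancies, age-band decompositions, Sullivan comparisons, plots, and a
text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import estimation, ingest, lifetable, mortality, sullivan
from .probability import TransitionProbabilitySet
from .states import (
    DECOMPOSITION_BANDS,
    MIN_AGE,
    STATE_LABELS,
    State,
)

__all__ = ["WorkingLifeModel", "WorkingLifeResults"]


class WorkingLifeModel:
    """Markov multistate working-life model estimated from transition records.

    Parameters
    ----------
    transitions : DataFrame with columns sex, age, year, occupation, origin,
        destination — one row per observed year-to-year transition.
    include_occupation : stratify by occupational category (dummies and
        occupation x year interactions); ``False`` reproduces a total-
        population analysis with a single stratum per sex.
    reference : optional :class:`~worklife.mortality.ReferenceLifeTable` (or
        mapping sex -> table) used to align aggregate mortality after fitting.
    """

    def __init__(
        self,
        transitions: pd.DataFrame,
        include_occupation: bool = True,
        occupation_year_interaction: bool = True,
        n_interior_knots: int = 5,
        ridge: float = 1e-6,
        reference=None,
    ):
        required = {"sex", "age", "year", "occupation", "origin", "destination"}
        missing = required - set(transitions.columns)
        if missing:
            raise ValueError(f"transition records lack columns {sorted(missing)}")
        self.transitions = transitions
        self.reference = reference
        self.config = estimation.ModelConfig(
            include_occupation=include_occupation,
            occupation_year_interaction=occupation_year_interaction,
            n_interior_knots=n_interior_knots,
            ridge=ridge,
        )

    @classmethod
    def from_spells(
        cls,
        spells: pd.DataFrame,
        deaths: pd.DataFrame | None = None,
        years: tuple[int, int] | None = None,
        **kwargs,
    ) -> "WorkingLifeModel":
        """Build the model from spell-level register records via ingestion."""
        _, transitions = ingest.ingest_spells(spells, deaths=deaths, years=years)
        return cls(transitions, **kwargs)

    def fit(self) -> "WorkingLifeResults":
        model_set = estimation.fit_transition_models(self.transitions, self.config)
        pset = estimation.predict_probability_set(model_set)
        adjustment = None
        if self.reference is not None:
            adjustment = mortality.adjust_probability_set(pset, self.reference)
            pset = adjustment.pset
        return WorkingLifeResults(
            model=self, model_set=model_set, probability_set=pset, adjustment=adjustment
        )


@dataclass
class WorkingLifeResults:
    """Fitted transition probabilities and the life-table quantities they imply."""

    model: WorkingLifeModel
    model_set: estimation.TransitionModelSet
    probability_set: TransitionProbabilitySet
    adjustment: mortality.AdjustmentResult | None = None

    # -- life-table queries -------------------------------------------------
    def occupancy(
        self, sex: str, occupation: str = "all", year: int | None = None, start_age: int = MIN_AGE,
        init_distribution=None,
    ) -> lifetable.OccupancyMatrix:
        return lifetable.state_occupancy(
            self.probability_set, sex, occupation, year, start_age, init_distribution
        )

    def expectancies(
        self, sex: str, occupation: str = "all", year: int | None = None, start_age: int = MIN_AGE,
        init_distribution=None,
    ) -> lifetable.StateExpectancySet:
        return lifetable.state_expectancies(
            self.occupancy(sex, occupation, year, start_age, init_distribution)
        )

    def expectancy_table(self, start_age: int = MIN_AGE) -> pd.DataFrame:
        """Expectancy-by-period table: one row per sex (x occupation) x period.

        Periods are labelled "t/t+1" because year-t transition probabilities
        describe the two adjacent calendar years.
        """
        rows = []
        pset = self.probability_set
        for sex in pset.sexes:
            for occ in pset.occupations:
                for year in pset.years:
                    e = self.expectancies(sex, occ, year, start_age)
                    row = {"sex": sex, "occupation": occ, "period": f"{year}/{year + 1}"}
                    row.update(e.as_dict())
                    rows.append(row)
        return pd.DataFrame(rows)

    def decompose(
        self,
        sex: str,
        occupation: str = "all",
        year: int | None = None,
        state: State | str = State.EMPLOYED,
        bands=DECOMPOSITION_BANDS,
        start_age: int = MIN_AGE,
    ) -> lifetable.AgeBandDecomposition:
        return lifetable.decompose_by_age_band(
            self.occupancy(sex, occupation, year, start_age), state, bands
        )

    def change_decomposition(
        self,
        sex: str,
        year1: int,
        year2: int,
        occupation: str = "all",
        state: State | str = State.EMPLOYED,
        bands=DECOMPOSITION_BANDS,
        start_age: int = MIN_AGE,
    ) -> lifetable.AgeBandDecomposition:
        return lifetable.change_decomposition(
            self.occupancy(sex, occupation, year1, start_age),
            self.occupancy(sex, occupation, year2, start_age),
            state,
            bands,
        )

    def awle_series(self, sex: str, occupation: str = "all", start_age: int = MIN_AGE) -> dict[int, float]:
        """Active working life expectancy (employed + unemployed) by period."""
        return {
            year: sullivan.awle(self.expectancies(sex, occupation, year, start_age))
            for year in self.probability_set.years
        }

    # -- presentation -------------------------------------------------------
    def summary(self, start_age: int = MIN_AGE) -> str:
        """Text summary in the spirit of statsmodels results."""
        lines = []
        lines.append("Markov multistate working-life model")
        lines.append("=" * 72)
        cfg = self.model_set.config
        lines.append(
            f"subsamples: {len(self.model_set.models)}   "
            f"occupation terms: {'yes' if cfg.include_occupation else 'no'}   "
            f"mortality alignment: {'yes' if self.adjustment is not None else 'no'}"
        )
        n_total = sum(m.n_obs for m in self.model_set.models.values())
        lines.append(f"transitions used: {n_total:,}")
        lines.append("")
        lines.append("log-likelihood by subsample (model vs intercept-only):")
        for (sex, band), m in sorted(self.model_set.models.items()):
            lines.append(
                f"  {sex:6s} {band[0]:>2d}-{band[1]:<2d}  n={m.n_obs:>9,}  "
                f"ll={m.loglike:>14.1f}  ll0={m.loglike_null:>14.1f}"
            )
        lines.append("")
        lines.append(f"remaining life expectancy at age {start_age} by state (years):")
        table = self.expectancy_table(start_age)
        with pd.option_context("display.float_format", lambda v: f"{v:6.1f}"):
            lines.append(table.to_string(index=False))
        return "\n".join(lines)

    def plot_expectancies(self, state: State | str = State.EMPLOYED, start_age: int = MIN_AGE, ax=None):
        """Line plot of a state expectancy by period, one line per stratum."""
        import matplotlib.pyplot as plt

        label = STATE_LABELS[state] if isinstance(state, State) else state
        table = self.expectancy_table(start_age)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for (sex, occ), grp in table.groupby(["sex", "occupation"]):
            name = sex if occ == "all" else f"{sex}, {occ}"
            ax.plot(grp["period"], grp[label], marker="o", label=name)
        ax.set_xlabel("period")
        ax.set_ylabel(f"years {label} from age {start_age}")
        ax.tick_params(axis="x", rotation=45)
        ax.legend(fontsize=8)
        return ax

    def plot_change_decomposition(self, sex: str, year1: int, year2: int, occupation: str = "all", ax=None):
        """Bar plot of the age-band decomposition of a change in WLE."""
        import matplotlib.pyplot as plt

        dec = self.change_decomposition(sex, year1, year2, occupation)
        ser = dec.as_series()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ser.plot.bar(ax=ax)
        ax.set_ylabel(f"years of WLE change, {year1} to {year2}")
        ax.axhline(0.0, color="black", linewidth=0.8)
        return ax
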