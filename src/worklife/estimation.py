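"""Multinomial transition-probability estimation on sex x age-band subsamples.

Destination state at t+1 is regressed on the origin state at t, a cubic
B-spline basis in age (five interior knots at the age quantiles of the band),
calendar-year indicators (first year as reference; the final data year never
appears as origin year), and — optionally — occupational-category indicators
with occupation x year interactions. The data are split into ten subsamples
(two sexes times five age bands: 15-29, 30-54, 55-64, 65-79, 80-99) and each
is fitted separately, which lets the age schedule break at band edges and
implicitly interacts age and sex with every covariate. A small ridge penalty
stabilises sparse cells against separation; destinations never observed in a
subsample get structural zero probability.

A raw-frequency tabulation (`empirical_probability_set`) provides the
model-free oracle for validation.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.linear_model import LogisticRegression

from .probability import TransitionProbabilitySet
from .states import (
    ESTIMATION_BANDS,
    MAX_AGE,
    MIN_AGE,
    MISSING_OCC,
    N_ALIVE,
    N_STATES,
    OCCUPATIONS,
    SEXES,
    STATE_FROM_LABEL,
    State,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SubsampleModel",
    "TransitionModelSet",
    "EmpiricalEstimate",
    "fit_transition_models",
    "predict_probability_set",
    "empirical_probability_set",
]


@dataclass
class ModelConfig:
    """Configuration of the subsample multinomial models."""

    include_occupation: bool = True
    occupation_year_interaction: bool = True
    n_interior_knots: int = 5
    spline_degree: int = 3
    #: L2 penalty per coefficient guarding against separation
    ridge: float = 1e-6
    max_iter: int = 400
    tol: float = 1e-7
    bands: tuple[tuple[int, int], ...] = ESTIMATION_BANDS


@dataclass
class _DesignInfo:
    """Frozen coding of one subsample's design matrix."""

    knots: np.ndarray  # full knot vector of the age spline
    degree: int
    origin_levels: list[int]  # observed origin state codes; first is reference
    year_levels: list[int]  # years with an indicator (reference year dropped)
    occ_levels: list[str]  # occupation categories with an indicator
    interaction: bool

    def build(self, ages, years, occs, origins) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        cols = [BSpline.design_matrix(np.clip(ages, self.knots[0], self.knots[-1]), self.knots, self.degree).toarray()]
        for lvl in self.origin_levels[1:]:
            cols.append((np.asarray(origins) == lvl).astype(float)[:, None])
        year_dummies = {y: (np.asarray(years) == y).astype(float) for y in self.year_levels}
        for y in self.year_levels:
            cols.append(year_dummies[y][:, None])
        for occ in self.occ_levels:
            occ_dummy = (np.asarray(occs) == occ).astype(float)
            cols.append(occ_dummy[:, None])
            if self.interaction:
                for y in self.year_levels:
                    cols.append((occ_dummy * year_dummies[y])[:, None])
        return np.hstack(cols)


@dataclass
class SubsampleModel:
    """Fitted multinomial model for one sex x age-band cell."""

    sex: str
    band: tuple[int, int]
    design: _DesignInfo
    classes: np.ndarray  # destination state codes in estimator order
    estimator: LogisticRegression | None
    n_obs: int
    loglike: float
    loglike_null: float

    def predict_proba(self, ages, years, occs, origins) -> np.ndarray:
        """Probabilities over all five destinations (unobserved ones are 0)."""
        n = len(np.atleast_1d(ages))
        out = np.zeros((n, N_STATES))
        if self.estimator is None:  # single observed destination
            out[:, int(self.classes[0])] = 1.0
            return out
        X = self.design.build(ages, years, occs, origins)
        proba = self.estimator.predict_proba(X)
        for k, cls in enumerate(self.classes):
            out[:, int(cls)] = proba[:, k]
        return out


@dataclass
class TransitionModelSet:
    """The complete set of per-subsample models plus the shared configuration."""

    models: dict[tuple[str, tuple[int, int]], SubsampleModel]
    config: ModelConfig
    years: tuple[int, ...]  # transition (origin) years covered
    occupations: tuple[str, ...]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "TransitionModelSet":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a TransitionModelSet")
        return obj


def _spline_knots(ages: np.ndarray, band: tuple[int, int], n_interior: int, degree: int) -> np.ndarray:
    lo, hi = float(band[0]), float(min(band[1], MAX_AGE))
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(ages, qs))
    interior = interior[(interior > lo) & (interior < hi)]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def fit_transition_models(
    records: pd.DataFrame,
    config: ModelConfig | None = None,
) -> TransitionModelSet:
    """Fit the ten subsample multinomial models.

    ``records`` needs columns sex, age, year, occupation, origin, destination
    (origin/destination as state labels). Records with a missing occupational
    category are dropped when occupation enters the model. The final data
    year is recognised as max(year) + 1 and receives no indicator because it
    never occurs as an origin year.
    """
    config = config or ModelConfig()
    df = records
    if config.include_occupation:
        n0 = len(df)
        df = df[df["occupation"] != MISSING_OCC]
        df = df[df["occupation"].notna()]
        if len(df) < n0:
            logger.info("dropped %d records with missing occupation", n0 - len(df))
    years = tuple(sorted(int(y) for y in df["year"].unique()))
    occupations = tuple(o for o in OCCUPATIONS if o in set(df["occupation"])) if config.include_occupation else ("all",)

    origin_codes = df["origin"].map(lambda s: int(STATE_FROM_LABEL[s])).to_numpy()
    dest_codes = df["destination"].map(lambda s: int(STATE_FROM_LABEL[s])).to_numpy()
    ages = df["age"].to_numpy()
    yrs = df["year"].to_numpy()
    occs = df["occupation"].to_numpy() if config.include_occupation else np.full(len(df), "all")
    sexes = df["sex"].to_numpy()

    models: dict[tuple[str, tuple[int, int]], SubsampleModel] = {}
    for sex in SEXES:
        for band in config.bands:
            lo, hi = band
            mask = (sexes == sex) & (ages >= lo) & (ages <= hi)
            if not mask.any():
                raise ValueError(f"no transition records in subsample (sex={sex}, ages {lo}-{hi})")
            models[(sex, band)] = _fit_subsample(
                sex,
                band,
                ages[mask],
                yrs[mask],
                occs[mask],
                origin_codes[mask],
                dest_codes[mask],
                years,
                config,
            )
    return TransitionModelSet(models=models, config=config, years=years, occupations=occupations)


def _fit_subsample(sex, band, ages, yrs, occs, origins, dests, all_years, config) -> SubsampleModel:
    classes = np.unique(dests)
    knots = _spline_knots(ages, band, config.n_interior_knots, config.spline_degree)
    observed_origins = sorted(np.unique(origins).tolist())
    year_levels = [y for y in all_years[1:] if (yrs == y).any()]
    occ_levels = (
        [o for o in OCCUPATIONS[1:] if (occs == o).any()] if config.include_occupation else []
    )
    design = _DesignInfo(
        knots=knots,
        degree=config.spline_degree,
        origin_levels=observed_origins,
        year_levels=year_levels,
        occ_levels=occ_levels,
        interaction=config.occupation_year_interaction and config.include_occupation,
    )
    n = len(ages)
    missing = set(range(N_STATES)) - set(classes.tolist()) - {int(State.DEAD) if band[1] < MAX_AGE else -1}
    if len(classes) < N_STATES:
        never = [s for s in range(N_STATES) if s not in classes]
        logger.warning(
            "subsample (%s, %d-%d): destinations %s never observed; structural zero",
            sex,
            band[0],
            band[1],
            never,
        )
    if len(classes) == 1:
        ll = 0.0
        return SubsampleModel(
            sex=sex,
            band=band,
            design=design,
            classes=classes,
            estimator=None,
            n_obs=n,
            loglike=ll,
            loglike_null=ll,
        )
    X = design.build(ages, yrs, occs, origins)
    est = LogisticRegression(
        C=1.0 / config.ridge,
        solver="lbfgs",
        max_iter=config.max_iter,
        tol=config.tol,
        fit_intercept=False,  # the spline basis spans the intercept
    )
    est.fit(X, dests)
    proba = est.predict_proba(X)
    row_p = proba[np.arange(n), np.searchsorted(est.classes_, dests)]
    loglike = float(np.log(np.clip(row_p, 1e-300, None)).sum())
    freq = np.bincount(np.searchsorted(classes, dests), minlength=len(classes)) / n
    loglike_null = float(n * np.sum(freq[freq > 0] * np.log(freq[freq > 0])))
    return SubsampleModel(
        sex=sex,
        band=band,
        design=design,
        classes=est.classes_,
        estimator=est,
        n_obs=n,
        loglike=loglike,
        loglike_null=loglike_null,
    )


def predict_probability_set(
    model_set: TransitionModelSet,
    years: tuple[int, ...] | None = None,
) -> TransitionProbabilitySet:
    """Materialise the fitted models on the full stratification grid.

    The grid covers sex x occupation x origin year x age 15-99 x origin x
    destination. Boundary rules (retired-only at destination ages 80-98,
    certain death at 99) are enforced afterwards and rows renormalised; the
    piecewise fit may jump at band edges by design.
    """
    years = years or model_set.years
    occupations = model_set.occupations
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    p = np.zeros((len(SEXES), len(occupations), len(years), len(ages), N_ALIVE, N_STATES))
    for si, sex in enumerate(SEXES):
        for band in model_set.config.bands:
            model = model_set.models[(sex, band)]
            band_ages = [a for a in ages if band[0] <= a <= band[1]]
            grid = [
                (a, y, occ, origin)
                for a in band_ages
                for y in years
                for occ in occupations
                for origin in range(N_ALIVE)
            ]
            ga = np.array([g[0] for g in grid], dtype=float)
            gy = np.array([g[1] for g in grid])
            go = np.array([g[2] for g in grid])
            gi = np.array([g[3] for g in grid])
            proba = model.predict_proba(ga, gy, go, gi)
            for row, (a, y, occ, origin) in enumerate(grid):
                p[si, occupations.index(occ), years.index(y), a - MIN_AGE, origin, :] = proba[row]
    pset = TransitionProbabilitySet(
        p=p,
        sexes=SEXES,
        occupations=occupations,
        years=tuple(int(y) for y in years),
        ages=ages,
        provenance="model-based",
    ).enforce_boundaries()
    pset.validate()
    return pset


@dataclass
class EmpiricalEstimate:
    """Raw frequency estimate: probabilities (NaN where unobserved) + exposure."""

    pset: TransitionProbabilitySet
    exposure: np.ndarray  # (sex, occ, year, age, origin)


def empirical_probability_set(records: pd.DataFrame) -> EmpiricalEstimate:
    """Raw transition frequencies per fully stratified cell.

    Cells with zero exposure are NaN (missing), not zero; the returned set is
    therefore not validated as a complete probability grid.
    """
    df = records
    occupations = tuple(o for o in OCCUPATIONS if o in set(df["occupation"]))
    if not occupations:
        occupations = ("all",)
        occ_idx = np.zeros(len(df), dtype=np.int64)
    else:
        occ_map = {o: i for i, o in enumerate(occupations)}
        occ_idx = df["occupation"].map(occ_map).to_numpy()
    years = tuple(sorted(int(y) for y in df["year"].unique()))
    year_map = {y: i for i, y in enumerate(years)}
    ages = np.arange(MIN_AGE, MAX_AGE + 1)

    counts = np.zeros((len(SEXES), len(occupations), len(years), len(ages), N_ALIVE, N_STATES))
    sex_idx = df["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()
    year_idx = df["year"].map(year_map).to_numpy()
    age_idx = df["age"].to_numpy() - MIN_AGE
    orig_idx = df["origin"].map(lambda s: int(STATE_FROM_LABEL[s])).to_numpy()
    dest_idx = df["destination"].map(lambda s: int(STATE_FROM_LABEL[s])).to_numpy()
    np.add.at(counts, (sex_idx, occ_idx, year_idx, age_idx, orig_idx, dest_idx), 1.0)

    exposure = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / exposure[..., None]
    pset = TransitionProbabilitySet(
        p=p,
        sexes=SEXES,
        occupations=occupations,
        years=years,
        ages=ages,
        provenance="empirical",
    )
    return EmpiricalEstimate(pset=pset, exposure=exposure)
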