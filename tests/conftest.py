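"""Shared fixtures: small regimes, simulated samples, random probability sets."""

from __future__ import annotations

import numpy as np
import pytest

from worklife import (
    RegimeParams,
    SyntheticConfig,
    build_truth_regime,
    simulate_trajectories,
)
from worklife.probability import TransitionProbabilitySet
from worklife.states import MAX_AGE, MIN_AGE, N_ALIVE, N_STATES, OCCUPATIONS, SEXES


@pytest.fixture(scope="session")
def small_regime():
    """Shock-free default regime over a short window."""
    return build_truth_regime(RegimeParams(years=(2004, 2008)))


@pytest.fixture(scope="session")
def crisis_regime():
    """Regime with a sharp employment shock from 2008 on."""
    return build_truth_regime(
        RegimeParams(years=(2004, 2013), crisis_year=2008, crisis_magnitude=1.0)
    )


@pytest.fixture(scope="session")
def sim_small(small_regime):
    """Small closed age-15 cohort with multi-spell expansion and missingness."""
    config = SyntheticConfig(
        n_individuals=2_000,
        years=(2004, 2008),
        seed=42,
        multi_spell_prob=0.6,
        missing_occupation_fraction=0.05,
    )
    return simulate_trajectories(small_regime, config)


@pytest.fixture(scope="session")
def sim_population(small_regime):
    """Stationary mixed-age population for estimation/prevalence tests."""
    config = SyntheticConfig(
        n_individuals=8_000,
        years=(2004, 2008),
        entry_age_range=(15, 95),
        entry_mode="stationary",
        seed=7,
    )
    return simulate_trajectories(small_regime, config)


def make_random_pset(seed: int, years=(2004, 2006)) -> TransitionProbabilitySet:
    """A random valid probability set (Dirichlet rows + boundary enforcement)."""
    rng = np.random.default_rng(seed)
    yr = tuple(range(years[0], years[1] + 1))
    n_age = MAX_AGE - MIN_AGE + 1
    shape = (len(SEXES), len(OCCUPATIONS), len(yr), n_age, N_ALIVE, N_STATES)
    p = rng.dirichlet(np.full(N_STATES, 0.5), size=shape[:-1])
    # keep mortality moderate so chains survive a while
    p[..., -1] *= 0.2
    p /= p.sum(axis=-1, keepdims=True)
    pset = TransitionProbabilitySet(
        p=p,
        sexes=SEXES,
        occupations=OCCUPATIONS,
        years=yr,
        ages=np.arange(MIN_AGE, MAX_AGE + 1),
        provenance="ground-truth",
    ).enforce_boundaries()
    pset.validate()
    return pset
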