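"""Occupancy, expectancies, fundamental-matrix oracle, decompositions."""

from dataclasses import replace

import numpy as np
import pytest

from worklife import (
    change_decomposition,
    decompose_by_age_band,
    expectancies_via_fundamental_matrix,
    simulate_state_paths,
    state_expectancies,
    state_occupancy,
)
from worklife.probability import TransitionProbabilitySet
from worklife.states import MAX_AGE, MIN_AGE, N_ALIVE, N_STATES, State

from conftest import make_random_pset


def _toy_pset(builder):
    """Build a single-stratum pset from a row-builder f(age, origin) -> row."""
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    p = np.zeros((1, 1, 1, len(ages), N_ALIVE, N_STATES))
    for ai, age in enumerate(ages):
        for origin in range(N_ALIVE):
            p[0, 0, 0, ai, origin] = builder(age, origin)
    return TransitionProbabilitySet(
        p=p, sexes=("male",), occupations=("all",), years=(2004,), ages=ages
    )


@pytest.fixture(scope="module")
def absorbing_toy():
    def rows(age, origin):
        row = np.zeros(N_STATES)
        row[int(State.DEAD)] = 1.0
        return row

    return _toy_pset(rows)


@pytest.fixture(scope="module")
def geometric_toy():
    """Employed retains 0.5, leavers go to (absorbing-alive) inactive; no
    death before 99 except the terminal wall, and inactive never dies ...
    except at 99 where death is structural."""

    def rows(age, origin):
        row = np.zeros(N_STATES)
        if age >= MAX_AGE:
            row[int(State.DEAD)] = 1.0
        elif origin == int(State.EMPLOYED):
            row[int(State.EMPLOYED)] = 0.5
            row[int(State.INACTIVE)] = 0.5
        else:
            row[int(State.INACTIVE)] = 1.0
        return row

    return _toy_pset(rows)


def _init(state):
    init = np.zeros(N_ALIVE)
    init[int(state)] = 1.0
    return init


class TestOccupancy:
    def test_absorbing_case_one_year_of_life(self, absorbing_toy):
        occ = state_occupancy(absorbing_toy, "male", "all", 2004, init_distribution=_init(State.INACTIVE))
        assert occ.pi[0, int(State.INACTIVE)] == 1.0
        assert occ.pi[1:].sum() == 0.0
        assert state_expectancies(occ).total == pytest.approx(1.0)

    def test_geometric_occupancy(self, geometric_toy):
        occ = state_occupancy(geometric_toy, "male", "all", 2004, init_distribution=_init(State.EMPLOYED))
        k = np.arange(len(occ.pi))
        assert np.abs(occ.pi[:, int(State.EMPLOYED)] - 0.5**k).max() < 1e-12

    def test_geometric_expectancy_closed_form(self, geometric_toy):
        e = state_expectancies(
            state_occupancy(geometric_toy, "male", "all", 2004, init_distribution=_init(State.EMPLOYED))
        )
        assert e[State.EMPLOYED] == pytest.approx(2.0 - 0.5**84, abs=1e-12)

    def test_survival_non_increasing(self, small_regime):
        occ = state_occupancy(small_regime.pset, "female", "skilled_nonmanual", 2005)
        assert np.all(np.diff(occ.survival) <= 1e-12)

    def test_no_alive_non_retired_at_80_plus(self, small_regime):
        occ = state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004)
        i80 = 80 - occ.start_age
        other = [int(State.EMPLOYED), int(State.UNEMPLOYED), int(State.INACTIVE)]
        assert np.abs(occ.pi[i80:, other]).max() == 0.0

    def test_unknown_stratum_raises_with_name(self, small_regime):
        with pytest.raises(KeyError, match="occupation='clerk'"):
            state_occupancy(small_regime.pset, "male", "clerk", 2004)

    def test_bad_init_distribution_rejected(self, small_regime):
        with pytest.raises(ValueError):
            state_occupancy(
                small_regime.pset, "male", "unskilled_manual", 2004,
                init_distribution=np.array([0.5, 0, 0, 0]),
            )


class TestAdditivity:
    def test_state_expectancies_sum_to_total(self, small_regime):
        for sex in ("male", "female"):
            e = state_expectancies(state_occupancy(small_regime.pset, sex, "skilled_manual", 2006))
            assert e.total == pytest.approx(float(e.expectancies.sum()), abs=1e-12)
            occ = state_occupancy(small_regime.pset, sex, "skilled_manual", 2006)
            assert e.total == pytest.approx(float(occ.pi.sum()), abs=1e-9)


class TestFundamentalMatrixOracle:
    def test_agrees_with_forward_propagation(self, small_regime):
        e1 = state_expectancies(state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004))
        e2 = expectancies_via_fundamental_matrix(small_regime.pset, "male", "unskilled_manual", 2004)
        assert np.abs(e1.expectancies - e2.expectancies).max() < 1e-10

    def test_absorbing_toy_total_one(self, absorbing_toy):
        e = expectancies_via_fundamental_matrix(
            absorbing_toy, "male", "all", 2004, init_distribution=_init(State.INACTIVE)
        )
        assert e.total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_regimes(self, seed):
        pset = make_random_pset(seed)
        e1 = state_expectancies(state_occupancy(pset, "male", "skilled_manual", 2005))
        e2 = expectancies_via_fundamental_matrix(pset, "male", "skilled_manual", 2005)
        assert np.abs(e1.expectancies - e2.expectancies).max() < 1e-10


class TestDecomposition:
    def test_whole_range_band_equals_expectancy(self, small_regime):
        occ = state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004)
        dec = decompose_by_age_band(occ, State.EMPLOYED, bands=((15, 99),))
        e = state_expectancies(occ)
        assert dec.total == pytest.approx(e[State.EMPLOYED], abs=1e-12)

    def test_geometric_first_year_band(self, geometric_toy):
        occ = state_occupancy(geometric_toy, "male", "all", 2004, init_distribution=_init(State.EMPLOYED))
        dec = decompose_by_age_band(occ, State.EMPLOYED, bands=((15, 15), (16, 99)))
        assert dec.contributions[(15, 15)] == pytest.approx(1.0)
        assert dec.contributions[(16, 99)] == pytest.approx(1.0 - 0.5**84)

    def test_band_contributions_sum_to_expectancy(self, small_regime):
        occ = state_occupancy(small_regime.pset, "female", "unskilled_nonmanual", 2007)
        e = state_expectancies(occ)
        for state in ("employed", "unemployed", "inactive", "retired"):
            dec = decompose_by_age_band(occ, state)
            assert dec.total == pytest.approx(e[state], abs=1e-9)

    def test_overlapping_bands_rejected(self, small_regime):
        occ = state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004)
        with pytest.raises(ValueError, match="overlap"):
            decompose_by_age_band(occ, State.EMPLOYED, bands=((15, 30), (30, 99)))

    def test_gap_in_bands_rejected(self, small_regime):
        occ = state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004)
        with pytest.raises(ValueError, match="cover"):
            decompose_by_age_band(occ, State.EMPLOYED, bands=((15, 30), (32, 99)))


class TestChangeDecomposition:
    def test_identical_periods_zero(self, small_regime):
        occ = state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004)
        dec = change_decomposition(occ, occ, State.EMPLOYED)
        assert all(v == 0.0 for v in dec.contributions.values())

    def test_sums_to_delta_wle(self, crisis_regime):
        o1 = state_occupancy(crisis_regime.pset, "male", "unskilled_manual", 2006)
        o2 = state_occupancy(crisis_regime.pset, "male", "unskilled_manual", 2008)
        dec = change_decomposition(o1, o2, State.EMPLOYED)
        delta = (
            state_expectancies(o2)[State.EMPLOYED] - state_expectancies(o1)[State.EMPLOYED]
        )
        assert dec.total == pytest.approx(delta, abs=1e-9)
        assert dec.total < -3.0  # the shock removes years of employment

    def test_targeted_youth_shock_concentrates_in_young_bands(self, small_regime):
        """A shock confined to young-age employment entry shows up (almost)
        only in the young bands of the change decomposition."""
        pset = small_regime.pset
        p = pset.p.copy()
        E, U, I = int(State.EMPLOYED), int(State.UNEMPLOYED), int(State.INACTIVE)
        # destroy employment entry from inactivity/unemployment below age 30
        for ai in range(0, 30 - MIN_AGE):
            for origin in (U, I):
                row = p[:, :, 1:, ai, origin, :]
                moved = row[..., E] * 0.9
                row[..., E] -= moved
                row[..., I] += moved
        shocked = replace(pset, p=p)
        o1 = state_occupancy(pset, "male", "unskilled_manual", 2004)
        o2 = state_occupancy(shocked, "male", "unskilled_manual", 2005)
        dec = change_decomposition(o1, o2, State.EMPLOYED)
        young = dec.contributions[(15, 19)] + dec.contributions[(20, 29)]
        assert dec.total < 0
        assert young / dec.total > 0.5

    def test_mismatched_grids_rejected(self, small_regime):
        o1 = state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004)
        o2 = state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004, start_age=20)
        with pytest.raises(ValueError):
            change_decomposition(o1, o2, State.EMPLOYED)


class TestMonteCarlo:
    def test_mean_years_in_state_match_analytic(self, small_regime):
        counts = simulate_state_paths(
            small_regime.pset, "male", "unskilled_manual", 2004, n_paths=200_000, seed=13
        )
        e = state_expectancies(state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004))
        mean = counts.mean(axis=0)
        se = counts.std(axis=0, ddof=1) / np.sqrt(len(counts))
        z = np.abs(mean - e.expectancies) / se
        assert z.max() < 3.5
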