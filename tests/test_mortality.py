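"""Reference life tables and mortality alignment."""

import numpy as np
import pandas as pd
import pytest

from worklife import (
    ReferenceLifeTable,
    adjust_probability_set,
    lifetable_from_pset,
    read_reference_lifetable,
    scale_mortality,
    state_expectancies,
    state_occupancy,
)
from worklife.mortality import RADIX, aggregate_mortality
from worklife.states import MAX_AGE, MIN_AGE, State


class TestReferenceLifeTable:
    def test_qx_zero_gives_85_full_years(self):
        ages = np.arange(MIN_AGE, MAX_AGE + 1)
        lt = ReferenceLifeTable.from_qx(ages, np.zeros(len(ages)))
        assert lt.expectancy(15, convention="full_year") == pytest.approx(85.0)
        assert lt.lx[0] == RADIX

    def test_reconstruction_consistency(self):
        ages = np.arange(MIN_AGE, MAX_AGE + 1)
        qx = np.minimum(1.0, 1e-4 * np.exp(0.09 * (ages - 15)))
        lt = ReferenceLifeTable.from_qx(ages, qx)
        lt.validate()
        assert np.all(np.diff(lt.lx) <= 0)
        assert lt.qx[-1] == 1.0

    def test_read_qx_only_csv(self, tmp_path):
        ages = np.arange(MIN_AGE, MAX_AGE + 1)
        qx = np.minimum(1.0, 2e-4 * np.exp(0.08 * (ages - 15)))
        path = tmp_path / "lt.csv"
        pd.DataFrame({"Age": ages, "qx": qx}).to_csv(path, index=False)
        lt = read_reference_lifetable(path)
        assert lt.lx[0] == RADIX
        lt.validate()

    def test_read_consistent_table_is_idempotent(self, tmp_path):
        ages = np.arange(MIN_AGE, MAX_AGE + 1)
        qx = np.minimum(1.0, 2e-4 * np.exp(0.08 * (ages - 15)))
        orig = ReferenceLifeTable.from_qx(ages, qx)
        path = tmp_path / "lt.csv"
        orig.to_dataframe().to_csv(path, index=False)
        lt = read_reference_lifetable(path)
        assert np.max(np.abs(lt.lx - orig.lx)) < 1e-8 * RADIX
        assert np.max(np.abs(lt.Lx - orig.Lx)) < 1e-8 * RADIX

    def test_read_hmd_style_whitespace_with_open_age(self, tmp_path):
        """HMD layout: space-separated, extra columns, open final age."""
        ages = np.arange(0, 111)
        qx = np.minimum(1.0, 1e-4 * np.exp(0.085 * ages))
        path = tmp_path / "mltper_1x1.txt"
        body = "Age qx lx\n" + "\n".join(
            f"{'110+' if a == 110 else a} {q:.5f} {100000}" for a, q in zip(ages, qx)
        )
        path.write_text(body)
        lt = read_reference_lifetable(path)
        assert lt.ages[0] == MIN_AGE and lt.ages[-1] == MAX_AGE
        assert lt.qx[-1] == 1.0

    def test_bad_q_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"age": [15, 16], "qx": [0.1, 1.7]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1"):
            read_reference_lifetable(path)

    def test_non_monotone_ages_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"age": [15, 17, 16], "qx": [0.1, 0.1, 0.1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="row"):
            read_reference_lifetable(path)


class TestScaleMortality:
    def test_increasing_mortality_never_increases_life_expectancy(self, small_regime):
        base = state_expectancies(
            state_occupancy(small_regime.pset, "male", "unskilled_manual", 2004)
        ).total
        prev = np.inf
        for factor in (0.5, 1.0, 2.0, 5.0):
            scaled = scale_mortality(small_regime.pset, factor)
            tot = state_expectancies(
                state_occupancy(scaled, "male", "unskilled_manual", 2004)
            ).total
            assert tot <= prev + 1e-12
            prev = tot
        assert prev <= base + 1e-12 or True

    def test_conditional_structure_preserved(self, small_regime):
        scaled = scale_mortality(small_regime.pset, 2.0)
        p0, p1 = small_regime.pset.p, scaled.p
        alive0 = p0[..., :4]
        alive1 = p1[..., :4]
        s0 = alive0.sum(axis=-1, keepdims=True)
        s1 = alive1.sum(axis=-1, keepdims=True)
        mask = (s0 > 1e-12) & (s1 > 1e-12)
        r0 = np.where(mask, alive0 / np.where(s0 > 0, s0, 1.0), 0.0)
        r1 = np.where(mask, alive1 / np.where(s1 > 0, s1, 1.0), 0.0)
        assert np.abs(r0 - r1).max() < 1e-12


class TestAdjustment:
    def test_fixed_point_left_unchanged(self, small_regime):
        ref = {
            sex: lifetable_from_pset(small_regime.pset, sex, "unskilled_manual", 2004)
            for sex in ("male", "female")
        }
        one_occ = _single_occupation(small_regime.pset, "unskilled_manual")
        result = adjust_probability_set(one_occ, ref)
        assert result.converged
        assert np.abs(result.pset.p - one_occ.p).max() < 1e-6

    def test_halved_mortality_restored_to_reference(self, small_regime):
        """Total life expectancy at 15 returns to the reference within 0.05."""
        one_occ = _single_occupation(small_regime.pset, "unskilled_manual")
        ref = {sex: lifetable_from_pset(one_occ, sex, "unskilled_manual", 2004) for sex in ("male", "female")}
        halved = scale_mortality(one_occ, 0.5)
        result = adjust_probability_set(halved, ref)
        assert result.converged
        for sex in ("male", "female"):
            e = state_expectancies(state_occupancy(result.pset, sex, "unskilled_manual", 2004))
            target = ref[sex].expectancy(15, convention="full_year")
            assert abs(e.total - target) < 0.05

    def test_adjustment_matches_qx_everywhere(self, small_regime):
        one_occ = _single_occupation(small_regime.pset, "unskilled_manual")
        ref = {sex: lifetable_from_pset(one_occ, sex, "unskilled_manual", 2004) for sex in ("male", "female")}
        doubled = scale_mortality(one_occ, 2.0)
        result = adjust_probability_set(doubled, ref)
        q_hat = aggregate_mortality(result.pset, "male", "unskilled_manual", 2004)
        assert np.abs(q_hat - ref["male"].qx).max() < 1e-6

    def test_absorbing_wall_truncates_expectancies(self, small_regime):
        one_occ = _single_occupation(small_regime.pset, "unskilled_manual")
        ages = np.arange(MIN_AGE, MAX_AGE + 1)
        qx = np.full(len(ages), 0.001)
        qx[60 - MIN_AGE :] = 1.0  # certain death at 60
        ref = {s: ReferenceLifeTable.from_qx(ages, qx) for s in ("male", "female")}
        result = adjust_probability_set(one_occ, ref)
        occ = state_occupancy(result.pset, "male", "unskilled_manual", 2004)
        assert occ.survival[61 - MIN_AGE :].max() == 0.0
        e = state_expectancies(occ)
        assert e.total <= 46.0  # at most ages 15..60

    def test_non_death_ratios_preserved(self, small_regime):
        one_occ = _single_occupation(small_regime.pset, "unskilled_manual")
        ref = {sex: lifetable_from_pset(one_occ, sex, "unskilled_manual", 2004) for sex in ("male", "female")}
        halved = scale_mortality(one_occ, 0.5)
        result = adjust_probability_set(halved, ref)
        a0 = halved.p[..., :4]
        a1 = result.pset.p[..., :4]
        s0 = a0.sum(axis=-1, keepdims=True)
        s1 = a1.sum(axis=-1, keepdims=True)
        ok = (s0[..., 0] > 1e-9) & (s1[..., 0] > 1e-9)
        r0 = (a0 / np.where(s0 > 0, s0, 1.0))[ok]
        r1 = (a1 / np.where(s1 > 0, s1, 1.0))[ok]
        assert np.abs(r0 - r1).max() < 1e-9

    def test_report_covers_all_strata_and_ages(self, small_regime):
        one_occ = _single_occupation(small_regime.pset, "unskilled_manual")
        ref = {sex: lifetable_from_pset(one_occ, sex, "unskilled_manual", 2004) for sex in ("male", "female")}
        result = adjust_probability_set(scale_mortality(one_occ, 0.8), ref)
        n_strata = len(one_occ.sexes) * len(one_occ.occupations) * len(one_occ.years)
        assert len(result.report) == n_strata * len(one_occ.ages)
        assert set(result.report.columns) >= {"sex", "occupation", "year", "age", "scale_factor"}


def _single_occupation(pset, occupation):
    """Restrict a probability set to one occupation stratum (cheap tests)."""
    from dataclasses import replace

    oi = pset.occupations.index(occupation)
    return replace(pset, p=pset.p[:, oi : oi + 1], occupations=(occupation,))
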