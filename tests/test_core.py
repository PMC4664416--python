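"""Forward prevalence recurrence, its inversion, and the mortality model."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from prevproj.core import (
    ConsistencyError,
    DegenerateCohortError,
    ExcessMortalityModel,
    NegativeIncidenceWarning,
    TreatmentShare,
    amplification_factor,
    apply_undiagnosed,
    backcalc_incidence,
    diabetic_death_risk,
    estimate_baseline,
    forward_prevalence_step,
    rr_at_year,
)
from prevproj.demography import N_AGES, AgeSexTable, MortalitySchedule


def valid_tuples():
    """Strategy over (p, m, m1, i) tuples satisfying the step's preconditions."""
    return st.tuples(
        st.floats(0.0, 0.95),   # p_prev
        st.floats(0.0, 0.5),    # m
        st.floats(1.0, 5.0),    # rr -> m1 via the mixture split
        st.floats(0.0, 1.0),    # i
    )


class TestForwardPrevalenceStep:
    @pytest.mark.parametrize(
        "p_prev,m,m1,i,expected",
        [
            (0.05, 0.0, 0.0, 0.0, 0.05),          # no deaths, no incidence
            (0.0, 0.0, 0.5, 0.004, 0.004),        # incidence only
            (0.05, 0.01, 0.02, 0.004, (0.98 * 0.05 + (0.99 - 0.049) * 0.004) / 0.99),
        ],
    )
    def test_hand_values(self, p_prev, m, m1, i, expected):
        assert forward_prevalence_step(p_prev, m, m1, i) == pytest.approx(expected, abs=1e-15)

    def test_extinct_cohort_rejected(self):
        with pytest.raises(ZeroDivisionError):
            forward_prevalence_step(0.5, 1.0, 0.5, 0.0)

    def test_more_surviving_cases_than_survivors_rejected(self):
        with pytest.raises(ConsistencyError):
            forward_prevalence_step(0.9, 0.5, 0.0, 0.0)

    @given(valid_tuples(), st.floats(0.0, 1.0))
    def test_monotone_in_incidence(self, tup, i2):
        p, m, rr, i1 = tup
        m1, _ = diabetic_death_risk(m, p, rr)
        lo, hi = sorted((i1, i2))
        assert forward_prevalence_step(p, m, m1, lo) <= forward_prevalence_step(p, m, m1, hi) + 1e-15

    @given(valid_tuples(), st.floats(0.0, 0.95))
    def test_monotone_in_previous_prevalence(self, tup, p2):
        p1, m, rr, i = tup
        lo, hi = sorted((p1, p2))
        m1_lo, _ = diabetic_death_risk(m, lo, rr)
        m1_hi, _ = diabetic_death_risk(m, hi, rr)
        assert forward_prevalence_step(lo, m, m1_lo, i) <= forward_prevalence_step(hi, m, m1_hi, i) + 1e-12

    @given(st.floats(0.0, 0.9), st.floats(0.0, 0.4), st.floats(0.0, 1.0))
    def test_higher_diabetic_mortality_never_raises_prevalence(self, p, m, i):
        m1_lo, m1_hi = m, min(2 * m + 0.05, 1.0)
        if (1 - m1_hi) * p > (1 - m):
            return
        assert (
            forward_prevalence_step(p, m, m1_hi, i)
            <= forward_prevalence_step(p, m, m1_lo, i) + 1e-15
        )

    @given(st.floats(0.0, 1.0), st.floats(0.0, 0.99))
    def test_no_incidence_equal_mortality_is_identity(self, p, m):
        assert forward_prevalence_step(p, m, m, 0.0) == pytest.approx(p, abs=1e-15)


class TestBackcalcIncidence:
    def test_stationary_prevalence_equal_mortality_gives_zero(self):
        assert backcalc_incidence(0.05, 0.05, 0.01, 0.01) == pytest.approx(0.0, abs=1e-15)

    def test_inverts_forward_example(self):
        p_now = forward_prevalence_step(0.05, 0.01, 0.02, 0.004)
        assert backcalc_incidence(p_now, 0.05, 0.01, 0.02) == pytest.approx(0.004, abs=1e-15)

    def test_empty_cohort_reduces_to_current_prevalence(self):
        assert backcalc_incidence(0.07, 0.0, 0.0, 0.3) == pytest.approx(0.07)

    def test_negative_incidence_warns_but_returns(self):
        with pytest.warns(NegativeIncidenceWarning):
            i = backcalc_incidence(0.0, 0.05, 0.0, 0.0)
        assert i < 0

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(DegenerateCohortError):
            backcalc_incidence(0.5, 1.0, 0.0, 0.0)

    @given(valid_tuples())
    def test_roundtrip_exact(self, tup):
        """backcalc(forward(p, m, m1, i)) == i to 1e-12 on valid tuples."""
        p, m, rr, i = tup
        m1, _ = diabetic_death_risk(m, p, rr)
        p_now = forward_prevalence_step(p, m, m1, i)
        assert backcalc_incidence(p_now, p, m, m1) == pytest.approx(i, abs=1e-12)


class TestDiabeticDeathRisk:
    def test_no_excess_risk_collapses(self):
        m1, m0 = diabetic_death_risk(0.01, 0.05, 1.0)
        assert m1 == 0.01 and m0 == 0.01

    def test_zero_prevalence_degenerate_mixture(self):
        m1, m0 = diabetic_death_risk(0.01, 0.0, 3.0)
        assert m0 == pytest.approx(0.01) and m1 == pytest.approx(0.03)

    def test_hand_solved_mixture(self):
        m1, m0 = diabetic_death_risk(0.01, 0.05, 3.0)
        assert m0 == pytest.approx(0.01 / 1.1, abs=1e-15)
        assert m1 == pytest.approx(3 * 0.01 / 1.1, abs=1e-15)

    @given(st.floats(0.0, 0.9), st.floats(0.0, 1.0), st.floats(1.0, 10.0))
    def test_mixture_identity_exact(self, m, p, rr):
        assume(rr * m / (1 + p * (rr - 1)) <= 1.0)  # outside this, m1 is clamped
        m1, m0 = diabetic_death_risk(m, p, rr)
        assert p * m1 + (1 - p) * m0 == pytest.approx(m, rel=1e-12, abs=1e-15)

    def test_vs_total_reference(self):
        m1, m0 = diabetic_death_risk(0.01, 0.05, 2.0, reference="vs_total")
        assert m1 == pytest.approx(0.02)
        assert 0.05 * m1 + 0.95 * m0 == pytest.approx(0.01)

    def test_vs_total_inconsistent_mixture_rejected(self):
        with pytest.raises(ConsistencyError):
            diabetic_death_risk(0.5, 0.9, 10.0, reference="vs_total")

    def test_rr_below_one_rejected(self):
        with pytest.raises(ValueError):
            diabetic_death_risk(0.01, 0.05, 0.5)


class TestExcessMortalityTrend:
    def test_no_elapsed_time_returns_baseline(self):
        em = ExcessMortalityModel(rr0=3.0, base_year=2013)
        assert rr_at_year(em, 0) == 3.0

    def test_excess_convention_one_year(self):
        em = ExcessMortalityModel(rr0=3.0, base_year=2013, annual_decline=0.016)
        assert em.rr_at(1) == pytest.approx(1 + 2 * 0.984)

    def test_excess_convention_approaches_one(self):
        em = ExcessMortalityModel(rr0=3.0, base_year=2013, annual_decline=0.016)
        assert em.rr_at(2000) == pytest.approx(1.0, abs=1e-10)

    def test_ratio_convention_floors_at_one(self):
        em = ExcessMortalityModel(rr0=3.0, base_year=2013, annual_decline=0.016, convention="ratio")
        assert em.rr_at(1) == pytest.approx(3 * 0.984)
        assert em.rr_at(2000) == 1.0

    def test_rr_below_one_baseline_rejected(self):
        with pytest.raises(ValueError):
            ExcessMortalityModel(rr0=0.9, base_year=2013)


class TestAmplificationFactor:
    def test_published_share_gives_printed_factor(self):
        assert amplification_factor(TreatmentShare(0.226)) == pytest.approx(1.292, abs=5e-4)

    @pytest.mark.parametrize("share,expected", [(0.0, 1.0), (0.5, 2.0)])
    def test_simple_shares(self, share, expected):
        assert amplification_factor(share) == expected

    @given(st.floats(0.0, 0.99))
    def test_factor_times_complement_is_one(self, s):
        assert amplification_factor(s) * (1 - s) == pytest.approx(1.0, abs=1e-12)

    def test_full_share_rejected(self):
        with pytest.raises(ValueError):
            amplification_factor(1.0)


class TestApplyUndiagnosed:
    def test_zero_share_is_identity(self):
        assert apply_undiagnosed(0.1, 0.0) == 0.1

    def test_of_total_convention(self):
        assert apply_undiagnosed(0.10, 0.366, "of_total") == pytest.approx(0.10 / 0.634)

    def test_of_diagnosed_convention(self):
        assert apply_undiagnosed(0.10, 0.366, "of_diagnosed") == pytest.approx(0.1366)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            apply_undiagnosed(0.1, 0.3, "bogus")


def _flat_tables(years, p_value, m_value):
    n = len(years)
    prev = AgeSexTable.from_grid(years, np.full((n, 2, N_AGES), p_value), "proportion")
    mort = MortalitySchedule.from_grid(years, np.full((n, 2, N_AGES), m_value), "risk")
    return prev, mort


class TestEstimateBaseline:
    def test_stationary_prevalence_gives_zero_incidence(self):
        prev, mort = _flat_tables(range(2007, 2014), 0.05, 0.01)
        em = ExcessMortalityModel(rr0=1.0, base_year=2007, annual_decline=0.0)
        out = estimate_baseline(prev, mort, em)
        vals = out.surface.values
        assert np.nanmax(np.abs(vals)) < 1e-14
        assert not out.negative_mask.any()

    def test_recovers_generator_incidence(self, country):
        """Inverting the forward-generated baseline recovers ground truth."""
        est = estimate_baseline(country.prevalence, country.mortality, country.excess_mortality)
        truth = country.incidence.at(country.spec.base_year)
        for iy in range(est.surface.years.size):
            got = est.surface.values[iy]
            ok = ~np.isnan(got)
            assert ok.sum() > 150
            np.testing.assert_allclose(got[ok], truth[ok], atol=1e-10)

    def test_impossible_decline_flagged(self):
        years = [2012, 2013]
        vals = np.stack([np.full((2, N_AGES), 0.05), np.zeros((2, N_AGES))])
        prev = AgeSexTable.from_grid(years, vals, "proportion")
        mort = MortalitySchedule.from_grid(years, np.zeros((2, 2, N_AGES)), "risk")
        em = ExcessMortalityModel(rr0=1.0, base_year=2012, annual_decline=0.0)
        out = estimate_baseline(prev, mort, em)
        assert out.negative_mask.any()
        assert (out.negative_cells()["value"] < 0).all()

    def test_year_gap_rejected(self):
        prev, mort = _flat_tables([2007, 2009], 0.05, 0.01)
        em = ExcessMortalityModel(rr0=1.0, base_year=2007)
        with pytest.raises(ValueError, match="gap"):
            estimate_baseline(prev, mort, em)

    def test_top_age_cells_skipped(self):
        prev, mort = _flat_tables([2012, 2013], 0.05, 0.01)
        em = ExcessMortalityModel(rr0=1.0, base_year=2012)
        out = estimate_baseline(prev, mort, em)
        assert np.isnan(out.surface.values[:, :, -1]).all()  # pooled 100+ bin
        assert np.isnan(out.surface.values[:, :, 0]).all()   # age 20 has no predecessor
        assert len(out.skipped_cells) == 2  # one top-age cell per sex
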