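"""Unit and property tests for the δ¹³C mixing and mass-balance operations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from strawtrace import (
    IsotopeEndMembers,
    StrawAmendment,
    allocation_fraction,
    atom_fraction_to_delta,
    delta_of_difference,
    delta_to_atom_fraction,
    delta_to_ratio,
    excess_13c_added,
    mbc_from_fumigation,
    pool_13c_mass,
    ratio_to_atom_fraction,
    ratio_to_delta,
    source_contribution,
    straw_13c_added,
)
from strawtrace.isotope import (
    DegenerateMixingError,
    InfeasibleMassBalanceError,
    InvalidDeltaError,
    InvalidRatioError,
    MixingRangeWarning,
    NegativeFlushError,
)

deltas = st.floats(min_value=-100.0, max_value=1000.0)


@pytest.mark.parametrize("delta, expected", [
    (0.0, 0.0112372),          # PDB standard by definition
    (-27.78, 0.0109250),       # study soil
    (357.48, 0.0152543),       # labelled straw
])
def test_delta_to_ratio_reference_points(delta, expected):
    assert delta_to_ratio(delta) == pytest.approx(expected, abs=5e-8)


@pytest.mark.parametrize("bad", [-1000.0, -1500.0, np.nan])
def test_delta_to_ratio_rejects_unphysical(bad):
    with pytest.raises(InvalidDeltaError):
        delta_to_ratio(bad)


@pytest.mark.parametrize("ratio, expected", [
    (0.0112372, 0.0111123),
    (1.0, 0.5),
    (1e-12, 1e-12),            # limit: fraction → ratio
])
def test_ratio_to_atom_fraction(ratio, expected):
    assert ratio_to_atom_fraction(ratio) == pytest.approx(expected, rel=1e-4)


def test_atom_fraction_rejects_nonpositive_ratio():
    with pytest.raises(InvalidRatioError):
        ratio_to_atom_fraction(0.0)
    with pytest.raises(InvalidRatioError):
        ratio_to_delta(-0.1)


@given(deltas)
def test_delta_ratio_atom_fraction_round_trip(delta):
    r = delta_to_ratio(delta)
    back = atom_fraction_to_delta(ratio_to_atom_fraction(r))
    assert back == pytest.approx(delta, abs=1e-9)


@pytest.mark.parametrize("c, delta, expected, tol", [
    (0.0, 357.48, 0.0, 1e-12),
    (1000.0, 0.0, 11.112, 5e-3),
    (10587.0, 357.48, 159.07, 5e-2),   # straw C added per kg soil
])
def test_pool_13c_mass(c, delta, expected, tol):
    assert pool_13c_mass(c, delta) == pytest.approx(expected, abs=tol)


class TestSourceContribution:
    def test_end_members_pin_0_and_100(self, end):
        assert source_contribution(end.delta_soil, end) == 0.0
        assert source_contribution(end.delta_straw, end) == 100.0

    def test_midpoint_is_half(self, end):
        mid = (end.delta_soil + end.delta_straw) / 2
        assert source_contribution(mid, end) == pytest.approx(50.0, abs=1e-12)

    def test_worked_value(self, end):
        assert source_contribution(49.272, end) == pytest.approx(20.0, abs=1e-3)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_affine_in_mixing_coefficient(self, end, a):
        delta = a * end.delta_soil + (1 - a) * end.delta_straw
        f = source_contribution(delta, end, warn=False)
        assert f == pytest.approx(100.0 * (1 - a), abs=1e-9)

    def test_degenerate_end_members_rejected(self):
        with pytest.raises(DegenerateMixingError):
            IsotopeEndMembers(delta_soil=-27.78, delta_straw=-27.78)

    def test_out_of_range_flagged_not_clipped(self, end):
        with pytest.warns(MixingRangeWarning):
            f = source_contribution(end.delta_straw + 50.0, end)
        assert f > 100.0

    def test_delta_vs_atom_space_agree_on_grid(self):
        # the two mixing spaces agree within 1.5% relative up to +400‰
        for delta_m in np.linspace(50.0, 400.0, 8):
            end = IsotopeEndMembers(-27.78, float(delta_m))
            for a in np.linspace(0.05, 0.95, 10):
                dsm = a * end.delta_straw + (1 - a) * end.delta_soil
                f_delta = source_contribution(dsm, end, warn=False)
                f_atom = source_contribution(dsm, end, space="atom", warn=False)
                assert f_delta == pytest.approx(f_atom, rel=0.015)


@pytest.mark.parametrize("cf, cn, k, expected", [
    (300.0, 300.0, 0.45, 0.0),
    (500.0, 300.0, 0.45, 444.44),
    (500.0, 300.0, 1.0, 200.0),
])
def test_mbc_from_fumigation(cf, cn, k, expected):
    assert mbc_from_fumigation(cf, cn, k) == pytest.approx(expected, abs=0.01)


def test_fumigation_errors():
    with pytest.raises(NegativeFlushError):
        mbc_from_fumigation(250.0, 300.0)
    with pytest.raises(ValueError):
        mbc_from_fumigation(500.0, 300.0, k_ec=0.0)


class TestDeltaOfDifference:
    def test_zero_part_returns_total(self):
        assert delta_of_difference(100.0, -20.0, 0.0, -10.0) == -20.0

    def test_uniform_isotopy(self):
        d = delta_of_difference(100.0, -20.0, 40.0, -20.0)
        assert d == pytest.approx(-20.0, abs=1e-9)

    def test_natural_abundance_example(self):
        # (100 units at −20‰) minus (40 units at −10‰): the δ-linear
        # approximation gives (−2000 + 400)/60 = −26.67‰
        d = delta_of_difference(100.0, -20.0, 40.0, -10.0)
        assert d == pytest.approx(-26.67, abs=0.01)

    def test_infeasible_mass_balance(self):
        with pytest.raises(InfeasibleMassBalanceError):
            delta_of_difference(100.0, -27.0, 100.0, -27.0)
        with pytest.raises(InfeasibleMassBalanceError):
            # the part holds more ¹³C than the total
            delta_of_difference(100.0, -27.0, 99.0, 900.0)

    @given(
        st.floats(min_value=10.0, max_value=1e4),
        st.floats(min_value=0.01, max_value=0.95),
        deltas, deltas,
    )
    def test_13c_conservation_on_remix(self, c_total, frac, d_total, d_part):
        """Splitting and re-mixing conserves ¹³C mass to 1e-9 relative."""
        c_part = frac * c_total
        m_total = pool_13c_mass(c_total, d_total)
        m_part = pool_13c_mass(c_part, d_part)
        if not 0 < m_total - m_part < (c_total - c_part):
            return  # infeasible split, rejected by the operation
        d_rem = delta_of_difference(c_total, d_total, c_part, d_part)
        m_rem = pool_13c_mass(c_total - c_part, d_rem)
        assert m_part + m_rem == pytest.approx(m_total, rel=1e-9)


class TestStrawAccounting:
    def test_excess_matches_hand_value(self, straw, end):
        assert excess_13c_added(straw, end) == pytest.approx(44.66, abs=0.01)

    def test_excess_linear_in_straw_mass(self, straw, end):
        double = StrawAmendment(2 * straw.straw_per_soil, straw.c_content,
                                straw.total_n, straw.delta)
        assert excess_13c_added(double, end) == pytest.approx(
            2 * excess_13c_added(straw, end), rel=1e-12)

    def test_excess_vanishes_as_end_members_merge(self, straw):
        end = IsotopeEndMembers(357.48 - 1e-6, 357.48)
        assert excess_13c_added(straw, end) == pytest.approx(0.0, abs=1e-6)

    def test_gross_exceeds_excess(self, straw, end):
        assert straw_13c_added(straw, end) > excess_13c_added(straw, end)


class TestAllocationFraction:
    def test_identical_arms_give_zero(self, straw, end):
        a = allocation_fraction(1000.0, -27.78, 1000.0, -27.78, straw, end)
        assert a == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("denominator", ["excess", "gross"])
    def test_known_straw_content_recovered(self, straw, end, denominator):
        """A pool holding S mg of straw C reports 100·S/total exactly."""
        s = 100.0
        native = 1000.0
        a_s = delta_to_atom_fraction(end.delta_soil)
        a_m = delta_to_atom_fraction(end.delta_straw)
        af = (native * a_s + s * a_m) / (native + s)
        d_am = atom_fraction_to_delta(af)
        got = allocation_fraction(native + s, d_am, native, end.delta_soil,
                                  straw, end, denominator=denominator)
        assert got == pytest.approx(100.0 * s / straw.c_added_mg_per_kg,
                                    rel=1e-9)

    def test_negative_excess_flagged(self, straw, end):
        with pytest.warns(MixingRangeWarning):
            a = allocation_fraction(1000.0, -30.0, 1000.0, -27.78, straw, end)
        assert a < 0.0
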