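"""Unit and property tests for the phase-duration calculator.

Non-trivial expected values were frozen from a 30-digit mpmath evaluation
of the closed forms (the independent oracle); trivial identities are
asserted directly.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orimin import (
    CcuBreakdown,
    DomainError,
    GrowthModel,
    InconsistentObservationError,
    LabelingTooLowError,
    PhaseDurations,
    PopulationSnapshot,
    estimate_all,
    to_ccu,
)
from orimin.cellcycle import (
    cumulative_time_to_phase_start,
    duration_cytokinesis,
    duration_g1,
    duration_g2,
    duration_mitosis,
    duration_s,
)


class TestGrowthModel:
    def test_growth_rate_is_ln2_over_doubling_time(self):
        g = GrowthModel(doubling_time=8.5)
        assert g.growth_rate == pytest.approx(math.log(2) / 8.5, rel=1e-15)

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_rejects_nonpositive_or_nonfinite_doubling_time(self, bad):
        with pytest.raises(DomainError):
            GrowthModel(doubling_time=bad)


class TestCumulativeTime:
    def test_limits_are_exact(self, growth24):
        # y=0 -> start of the cycle; y=1 -> the full doubling time
        assert cumulative_time_to_phase_start(0.0, growth24) == 0.0
        assert cumulative_time_to_phase_start(1.0, growth24) == pytest.approx(
            24.0, rel=1e-12
        )

    def test_frozen_oracle_value(self, growth24):
        # -ln(0.525) * 24 / ln 2, mpmath 30 digits
        assert cumulative_time_to_phase_start(0.95, growth24) == pytest.approx(
            22.3106561306064494, abs=1e-9
        )

    @pytest.mark.parametrize("y", [-0.01, 1.01, math.nan])
    def test_domain_errors(self, y, growth24):
        with pytest.raises(DomainError):
            cumulative_time_to_phase_start(y, growth24)

    @given(st.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing_in_y(self, y):
        g = GrowthModel(24.0)
        assert cumulative_time_to_phase_start(
            y + 1e-3, g
        ) > cumulative_time_to_phase_start(y, g)


class TestTerminalPhases:
    def test_no_cells_in_cytokinesis_means_zero_duration(self, growth24):
        assert duration_cytokinesis(0.0, growth24) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_cytokinesis_value(self, growth24):
        # 24 - (-ln(0.525) * 24 / ln 2), mpmath oracle
        assert duration_cytokinesis(0.05, growth24) == pytest.approx(
            1.68934386939355058, abs=1e-9
        )

    def test_whole_population_dividing_rejected(self, growth24):
        with pytest.raises(DomainError):
            duration_cytokinesis(1.0, growth24)

    def test_cytokinesis_strictly_increasing_in_fraction(self, growth24):
        values = [duration_cytokinesis(f, growth24) for f in (0.01, 0.05, 0.2, 0.6)]
        assert values == sorted(values) and len(set(values)) == len(values)

    def test_no_pure_mitosis_cells_means_zero_mitosis(self, growth24):
        c = duration_cytokinesis(0.05, growth24)
        assert duration_mitosis(0.05, c, growth24) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_mitosis_value(self, growth24):
        # (24 - (-ln(0.55)*24/ln2)) - C(0.05), mpmath oracle
        c = duration_cytokinesis(0.05, growth24)
        assert duration_mitosis(0.10, c, growth24) == pytest.approx(
            1.61074070060488722, abs=1e-9
        )

    def test_mc_fraction_below_c_fraction_is_inconsistent(self, growth24):
        c = duration_cytokinesis(0.10, growth24)
        with pytest.raises(InconsistentObservationError):
            duration_mitosis(0.05, c, growth24)


class TestG2:
    def test_two_nuclei_time_equal_to_mitosis_gives_zero(self):
        assert duration_g2(0.75, 0.75) == 0.0

    def test_plain_subtraction(self):
        assert duration_g2(2.0, 0.75) == pytest.approx(1.25)

    def test_chase_shorter_than_mitosis_is_inconsistent(self):
        with pytest.raises(InconsistentObservationError):
            duration_g2(0.5, 0.75)


class TestSPhase:
    def test_forward_model_round_trip(self, growth24):
        # L built from the closed form for S=9.86, Z=8.23, t=0.5 inverts back
        alpha = growth24.growth_rate
        lab = math.exp(alpha * (9.86 + 8.23 + 0.5)) - math.exp(alpha * 8.23)
        assert lab == pytest.approx(0.4423777753771336, abs=1e-12)
        assert duration_s(lab, 8.23, 0.5, growth24) == pytest.approx(9.86, abs=1e-6)

    def test_zero_labeling_raises_labeling_too_low(self, growth24):
        with pytest.raises(LabelingTooLowError):
            duration_s(0.0, 8.23, 0.5, growth24)

    def test_full_labeling_fills_cycle_as_pulse_vanishes(self, growth24):
        # L = 2 - e^{alpha Z} labels every cycling cell; S -> T - Z as t -> 0+
        alpha = growth24.growth_rate
        z = 8.23
        lab = 2.0 - math.exp(alpha * z)
        s = duration_s(lab, z, 1e-9, growth24)
        assert s == pytest.approx(24.0 - z, abs=1e-6)

    def test_overfull_labeling_is_inconsistent(self, growth24):
        with pytest.raises(InconsistentObservationError):
            duration_s(0.9, 8.23, 2.0, growth24)

    def test_strictly_increasing_in_labeled_fraction(self, growth24):
        values = [duration_s(lab, 8.23, 0.5, growth24) for lab in (0.2, 0.3, 0.4, 0.5)]
        assert values == sorted(values) and len(set(values)) == len(values)

    @given(
        s_true=st.floats(min_value=0.5, max_value=10.0),
        z=st.floats(min_value=0.5, max_value=9.0),
        t=st.floats(min_value=0.05, max_value=0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_stanners_till_self_inversion(self, s_true, z, t):
        """Closed-form L followed by duration_s recovers S to 1e-9 h."""
        g = GrowthModel(24.0)
        alpha = g.growth_rate
        lab = math.exp(alpha * (s_true + z + t)) - math.exp(alpha * z)
        assert duration_s(lab, z, t, g) == pytest.approx(s_true, abs=1e-9)


class TestG1:
    def test_exhausted_cycle_gives_zero(self, growth24):
        assert duration_g1(15.77, 8.23, growth24) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "t, s, z, expected",
        [
            (24.0, 9.86, 8.23, 5.91),  # 24 h trypanosomatid
            (8.5, 2.31, 2.82, 3.37),  # 8.5 h trypanosomatid
        ],
    )
    def test_published_g1_arithmetic(self, t, s, z, expected):
        assert duration_g1(s, z, GrowthModel(t)) == pytest.approx(expected, abs=1e-9)

    def test_negative_g1_is_inconsistent(self, growth24):
        with pytest.raises(InconsistentObservationError):
            duration_g1(20.0, 8.0, growth24)


class TestEstimateAll:
    def test_degenerate_population_reports_stage(self, growth24):
        snap = PopulationSnapshot(0.0, 0.0, 0.0, 0.5, 2.0)
        with pytest.raises(LabelingTooLowError, match="^S:"):
            estimate_all(snap, growth24)

    def test_phase_order_and_invariants(self, growth24):
        snap = PopulationSnapshot(0.05, 0.10, 0.44236, 0.5, 2.0)
        est = estimate_all(snap, growth24)
        assert est.z == pytest.approx(est.g2 + est.m + est.c, rel=1e-15)
        assert est.total == pytest.approx(24.0, abs=1e-9)
        assert all(v >= 0 for v in est.as_dict().values())


class TestCcu:
    @pytest.mark.parametrize(
        "hours, t, expected",
        [(9.86, 24.0, 0.411), (2.31, 8.5, 0.272)],
    )
    def test_published_s_phase_ccu(self, hours, t, expected):
        # rounding to 3 d.p. reproduces the published cell-cycle-unit values
        assert round(hours / t, 3) == expected

    def test_breakdown_sums_to_one(self, growth24):
        d = PhaseDurations(g1=5.91, s=9.86, g2=1.25, m=0.75, c=6.23)
        ccu = to_ccu(d, growth24)
        assert sum(ccu.as_dict().values()) == pytest.approx(1.0, abs=1e-9)
        assert ccu.s == pytest.approx(9.86 / 24.0, rel=1e-12)

    def test_single_phase_cycle_gives_unit_fraction(self):
        d = PhaseDurations(g1=0.0, s=24.0, g2=0.0, m=0.0, c=0.0)
        assert to_ccu(d, GrowthModel(24.0)).s == 1.0

    def test_mismatched_total_rejected(self, growth24):
        with pytest.raises(InconsistentObservationError):
            to_ccu(PhaseDurations(g1=1.0, s=1.0, g2=1.0, m=1.0, c=1.0), growth24)

    def test_breakdown_validates_sum(self):
        with pytest.raises(DomainError):
            CcuBreakdown(g1=0.5, s=0.2, g2=0.1, m=0.05, c=0.05)


class TestSnapshotValidation:
    def test_nested_fraction_violation(self):
        with pytest.raises(InconsistentObservationError):
            PopulationSnapshot(0.10, 0.05, 0.4, 0.5, 2.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_cytokinesis": 1.0},
            {"frac_edu_labeled": 1.5},
            {"pulse_duration": 0.0},
            {"time_to_two_labeled_nuclei": -1.0},
        ],
    )
    def test_out_of_range_fields(self, kwargs):
        base = dict(
            frac_cytokinesis=0.05,
            frac_mitosis_plus_cyto=0.10,
            frac_edu_labeled=0.4,
            pulse_duration=0.5,
            time_to_two_labeled_nuclei=2.0,
        )
        base.update(kwargs)
        with pytest.raises(DomainError):
            PopulationSnapshot(**base)
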