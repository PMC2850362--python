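"""Time shifts, survival fractions, cleaning, integrals, lineages."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from outgrowth.curves import CurveParams, ODCurve
from outgrowth.io import OutgrowthRun, RawRunTable, WellInfo
from outgrowth.simulate import SimSpec, simulate_tables
from outgrowth.survival import (
    AnalysisError,
    build_lineages,
    clean_survival,
    survival_fraction,
    survival_integral,
    time_shift,
)


class TestTimeShift:
    def test_identical_curves(self, exp_curve):
        c = exp_curve(delta=1.5)
        assert time_shift(c, c, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_exact_delay(self, exp_curve):
        ref = exp_curve(delta=1.5)
        delayed = exp_curve(delta=1.5, lag=3.0)
        assert time_shift(delayed, ref, 0.3) == pytest.approx(3.0, abs=1e-9)

    def test_dead_culture_is_absent(self, exp_curve):
        t = np.arange(0, 24, 0.5)
        flat = ODCurve(t, np.full_like(t, 0.15), background=0.15)
        assert time_shift(flat, exp_curve(), 0.3) is None

    def test_failed_reference_raises(self, exp_curve):
        t = np.arange(0, 24, 0.5)
        flat = ODCurve(t, np.full_like(t, 0.15), background=0.15)
        with pytest.raises(AnalysisError, match="reference outgrowth failed"):
            time_shift(exp_curve(), flat, 0.3)

    def test_different_grids_allowed(self, exp_curve):
        ref = exp_curve(delta=1.5, step=0.5)
        other = exp_curve(delta=1.5, step=0.25, lag=2.0)
        assert time_shift(other, ref, 0.3) == pytest.approx(2.0, abs=1e-9)


class TestSurvivalFraction:
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_each_doubling_of_delay_halves_survival(self, k):
        delta = 1.7
        assert survival_fraction(k * delta, delta) == 2.0 ** (-k)

    def test_hand_example(self):
        assert survival_fraction(3.0, 2.0) == pytest.approx(2.0 ** -1.5)

    def test_dead_culture_scores_zero(self):
        assert survival_fraction(None, 2.0) == 0.0

    def test_negative_shift_exceeds_one(self):
        assert survival_fraction(-1.0, 2.0) > 1.0


class TestCleanSurvival:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([1.0, 0.8, 0.9, 0.4], [1.0, 0.8, 0.8, 0.4]),
            ([1.0, 0.5, 0.2, 0.6], [1.0, 0.5, 0.2, 0.2]),  # terminal gasping
            ([1.0, 0.7, 0.3, 0.1], [1.0, 0.7, 0.3, 0.1]),
            ([0.8, 1.3, 0.5], [1.0, 1.0, 0.5]),  # first entry pinned to 1
        ],
    )
    def test_running_minimum(self, raw, expected):
        assert clean_survival(raw) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clean_survival([])

    @given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=12))
    def test_monotone_bounded_idempotent(self, raw):
        out = clean_survival(raw)
        assert out[0] == 1.0
        assert all(0.0 <= v <= 1.0 for v in out)
        assert all(a >= b for a, b in zip(out, out[1:]))
        assert clean_survival(out) == out


class TestSurvivalIntegral:
    def test_hand_trapezoid(self):
        assert survival_integral([2, 4, 6], [1.0, 0.5, 0.25]) == pytest.approx(2.25)

    def test_unit_survival_over_span(self):
        assert survival_integral([0, 11], [1.0, 1.0]) == pytest.approx(11.0)

    def test_uneven_spacing(self):
        assert survival_integral([2, 4, 9], [1.0, 1.0, 1.0]) == pytest.approx(7.0)

    def test_needs_two_age_points(self):
        with pytest.raises(ValueError):
            survival_integral([2], [1.0])

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8))
    def test_monotone_in_pointwise_ordering(self, s):
        days = list(range(2, 2 + len(s)))
        lower = survival_integral(days, s)
        upper = survival_integral(days, [min(1.0, v + 0.1) for v in s])
        assert upper >= lower - 1e-12


def _runs_from_sim(sim):
    return [OutgrowthRun(table=t, day=d, background=0.15) for d, t in sim.tables]


class TestBuildLineages:
    def test_identical_runs_full_survival(self, exp_curve):
        curve = exp_curve(delta=1.5)
        table = RawRunTable("r", curve.times, curve.od_raw[None, :])
        runs = [
            OutgrowthRun(table=table, day=2.0, background=0.0),
            OutgrowthRun(table=table, day=6.0, background=0.0),
        ]
        (ln,) = build_lineages(runs, None, CurveParams())
        assert ln.survival_clean == pytest.approx([1.0, 1.0])
        assert ln.survival_integral == pytest.approx(4.0)
        assert ln.ref_doubling_time.delta == pytest.approx(1.5, rel=1e-9)

    def test_dead_well_scores_zero_from_death_onward(self, exp_curve):
        live = exp_curve(delta=1.5)
        flat = np.full_like(live.times, 0.0)
        t1 = RawRunTable("a", live.times, live.od_raw[None, :])
        t2 = RawRunTable("b", live.times, flat[None, :])
        runs = [
            OutgrowthRun(table=t1, day=2.0, background=0.0),
            OutgrowthRun(table=t2, day=4.0, background=0.0),
            OutgrowthRun(table=t2, day=6.0, background=0.0),
        ]
        (ln,) = build_lineages(runs, None, CurveParams())
        assert ln.survival_clean == pytest.approx([1.0, 0.0, 0.0])
        assert ln.points[1].time_shift is None

    def test_simulated_viabilities_recovered(self):
        spec = SimSpec(
            noise_sd=0.0,
            viability_schedule=((2.0, 1.0), (5.0, 0.5), (8.0, 0.1)),
        )
        sim = simulate_tables(spec, n_replicate_wells=1)
        lineages = build_lineages(_runs_from_sim(sim), list(sim.wells), CurveParams())
        (ln,) = lineages
        for got, want in zip(ln.survival_clean, [1.0, 0.5, 0.1]):
            assert got == pytest.approx(want, rel=0.05)

    def test_blank_wells_skipped(self):
        sim = simulate_tables(SimSpec(noise_sd=0.0), n_replicate_wells=2)
        lineages = build_lineages(_runs_from_sim(sim), list(sim.wells), CurveParams())
        assert [ln.well_position for ln in lineages] == [1, 2]

    def test_unsorted_days_rejected(self, exp_curve):
        curve = exp_curve()
        table = RawRunTable("r", curve.times, curve.od_raw[None, :])
        runs = [
            OutgrowthRun(table=table, day=6.0, background=0.0),
            OutgrowthRun(table=table, day=2.0, background=0.0),
        ]
        with pytest.raises(AnalysisError, match="sorted"):
            build_lineages(runs, None)

    def test_failure_tagged_with_well_and_day(self):
        t = np.arange(0, 24, 0.5)
        flat = np.full_like(t, 0.15)[None, :]
        table = RawRunTable("r", t, flat)
        runs = [
            OutgrowthRun(table=table, day=2.0, background=0.15),
            OutgrowthRun(table=table, day=4.0, background=0.15),
        ]
        with pytest.raises(AnalysisError, match=r"well 1 .*day 2"):
            build_lineages(runs, None)

    def test_noise_free_dilution_series_recovery(self):
        """A lineage diluted 2**-k at age k is scored s = 2**-k to <=1%."""
        ks = [0, 1, 2, 3, 4]
        schedule = tuple((float(2 + 2 * k), 2.0 ** -k) for k in ks)
        spec = SimSpec(noise_sd=0.0, viability_schedule=schedule)
        sim = simulate_tables(spec, n_replicate_wells=1)
        (ln,) = build_lineages(_runs_from_sim(sim), list(sim.wells), CurveParams())
        for got, k in zip(ln.survival_clean, ks):
            assert got == pytest.approx(2.0 ** -k, rel=0.01)
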