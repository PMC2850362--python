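"""Properties of the synthetic outgrowth generator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from outgrowth.curves import CurveParams, crossing_time
from outgrowth.io import OutgrowthRun, parse_run, parse_well_info
from outgrowth.simulate import (
    DEFAULT_SCHEDULE,
    SimSpec,
    simulate_curve,
    simulate_experiment,
    simulate_tables,
)
from outgrowth.survival import build_lineages


class TestSimulateCurve:
    def test_saturates_at_carrying_capacity(self):
        spec = SimSpec(noise_sd=0.0, duration=48.0)
        curve = simulate_curve(spec)
        assert curve.od_corr[-1] == pytest.approx(spec.carrying_capacity, rel=1e-6)

    def test_half_viability_delays_by_one_doubling_time(self):
        spec = SimSpec(noise_sd=0.0, inoculum_od=0.01)
        full = simulate_curve(spec, 1.0)
        half = simulate_curve(spec, 0.5)
        shift = crossing_time(half, 0.1) - crossing_time(full, 0.1)
        assert shift == pytest.approx(spec.doubling_time, rel=0.01)

    def test_zero_viability_is_flat_background(self):
        spec = SimSpec(noise_sd=0.0)
        curve = simulate_curve(spec, 0.0)
        assert np.all(curve.od_raw == spec.background)

    def test_same_seed_reproduces_series(self):
        spec = SimSpec(noise_sd=0.01, seed=42)
        a = simulate_curve(spec)
        b = simulate_curve(spec)
        assert np.array_equal(a.od_raw, b.od_raw)

    def test_exponential_regime_doubles_every_delta(self):
        spec = SimSpec(noise_sd=0.0, doubling_time=2.0, inoculum_od=0.001)
        curve = simulate_curve(spec)
        i = np.searchsorted(curve.times, 4.0)
        ratio = curve.od_corr[i + 4] / curve.od_corr[i]  # 2 h apart
        assert ratio == pytest.approx(2.0, rel=1e-4)


class TestSimulateExperiment:
    def test_written_files_parse_with_expected_shape(self, tmp_path):
        spec = SimSpec(noise_sd=0.0)
        run_paths, wells_path, truth_path = simulate_experiment(
            spec, tmp_path, n_replicate_wells=3,
            groups={"WT": DEFAULT_SCHEDULE, "mut": DEFAULT_SCHEDULE},
        )
        assert len(run_paths) == 6
        wells = parse_well_info(wells_path)
        assert len(wells) == 7  # 2 groups x 3 replicates + 1 blank
        assert sum(1 for w in wells if w.role == "blank") == 1
        for _day, path in run_paths:
            table = parse_run(path)
            assert table.n_wells == 7
            assert table.times.size == spec.times.size
        truth = pd.read_csv(truth_path)
        assert len(truth) == 6 * 6  # sample wells x days

    def test_well_order_identical_across_runs(self, tmp_path):
        run_paths, wells_path, _ = simulate_experiment(
            SimSpec(noise_sd=0.0), tmp_path, n_replicate_wells=2
        )
        headers = set()
        for _day, path in run_paths:
            headers.add(path.read_text().splitlines()[0])
        assert len(headers) == 1

    def test_capacity_enforced(self, tmp_path):
        with pytest.raises(ValueError, match="capacity"):
            simulate_tables(SimSpec(), n_replicate_wells=100,
                            groups={"a": DEFAULT_SCHEDULE, "b": DEFAULT_SCHEDULE})

    def test_groups_must_share_day_grid(self):
        with pytest.raises(ValueError, match="same age-point days"):
            simulate_tables(
                SimSpec(),
                groups={"a": ((2.0, 1.0), (4.0, 0.5)), "b": ((2.0, 1.0), (5.0, 0.5))},
            )

    def test_noise_free_recovery_within_1pct(self):
        """Programmed viable fractions down to 1% come back as cleaned
        survival within 1% relative error without noise."""
        schedule = ((2.0, 1.0), (4.0, 0.6), (6.0, 0.25), (9.0, 0.08), (11.0, 0.01))
        spec = SimSpec(noise_sd=0.0, viability_schedule=schedule)
        sim = simulate_tables(spec, n_replicate_wells=1)
        runs = [OutgrowthRun(table=t, day=d, background=spec.background) for d, t in sim.tables]
        (ln,) = build_lineages(runs, list(sim.wells), CurveParams())
        for got, (_d, want) in zip(ln.survival_clean, schedule):
            assert got == pytest.approx(want, rel=0.01)

    def test_noisy_triplicate_group_means_within_10pct(self):
        """With read noise of 0.005 OD and triplicates, group-mean survival
        tracks the programmed fractions within 10% across 50 seeds."""
        schedule = ((2.0, 1.0), (6.0, 0.5), (10.0, 0.1))
        rel_errs = []
        for seed in range(50):
            spec = SimSpec(noise_sd=0.005, seed=seed, viability_schedule=schedule)
            sim = simulate_tables(spec, n_replicate_wells=3)
            runs = [
                OutgrowthRun(table=t, day=d, background=spec.background)
                for d, t in sim.tables
            ]
            lineages = build_lineages(runs, list(sim.wells), CurveParams())
            for i, (_d, want) in enumerate(schedule[1:], start=1):
                mean = np.mean([ln.survival_clean[i] for ln in lineages])
                rel_errs.append(abs(mean - want) / want)
        assert float(np.median(rel_errs)) <= 0.10
        assert float(np.mean(rel_errs)) <= 0.10

    def test_monotone_schedule_recovers_monotone_survival(self):
        """Treatments-as-age-points: a monotone viability schedule (e.g.
        increasing heat-shock duration) yields monotone cleaned survival."""
        schedule = tuple(
            (float(m), f) for m, f in [(0, 1.0), (5, 0.7), (10, 0.3), (15, 0.08), (20, 0.02)]
        )
        spec = SimSpec(noise_sd=0.003, seed=7, viability_schedule=schedule)
        sim = simulate_tables(spec, n_replicate_wells=3)
        runs = [
            OutgrowthRun(table=t, day=d, background=spec.background)
            for d, t in sim.tables
        ]
        for ln in build_lineages(runs, list(sim.wells), CurveParams()):
            s = ln.survival_clean
            assert all(a >= b for a, b in zip(s, s[1:]))
            assert s == pytest.approx([f for _d, f in schedule], rel=0.2)
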