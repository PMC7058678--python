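import datetime as dt

import numpy as np
import pytest

import wardsim as ws
from wardsim.engine import SimulationResult
from wardsim.records import CensusTrajectory
from wardsim.synthetic import GroundTruthConfig
from wardsim.validation import DeltaSampleSet, ValidationError, run_validation_windows

from conftest import MON, day


def census_from_series(series, ward="A"):
    counts = np.zeros((1, len(series), 2), dtype=int)
    counts[0, :, 0] = series
    return CensusTrajectory([ward], MON, counts)


class TestObservedDeltas:
    def test_hand_computed_example(self):
        deltas = ws.observed_deltas(census_from_series([5, 7, 4]), "A", 2)
        assert sorted(deltas.deltas[1].tolist()) == [-2, 3]
        assert deltas.deltas[2].tolist() == [1]

    def test_constant_series_gives_zero_deltas(self):
        deltas = ws.observed_deltas(census_from_series([3] * 10), "A", 6)
        assert all((v == 0).all() for v in deltas.deltas.values())

    def test_sample_sizes(self):
        deltas = ws.observed_deltas(census_from_series(list(range(20))), "A", 6)
        for h in range(1, 7):
            assert len(deltas.deltas[h]) == 20 - h

    def test_horizon_must_fit_series(self):
        with pytest.raises(ValidationError):
            ws.observed_deltas(census_from_series([1, 2]), "A", 2)

    def test_antisymmetry_under_time_reversal(self):
        rng = np.random.default_rng(2)
        series = rng.integers(0, 20, size=40)
        fwd = ws.observed_deltas(census_from_series(series), "A", 5)
        rev = ws.observed_deltas(census_from_series(series[::-1]), "A", 5)
        for h in range(1, 6):
            assert sorted(fwd.deltas[h].tolist()) == sorted((-rev.deltas[h]).tolist())


class TestPPPlot:
    def test_identical_samples_on_identity(self):
        a = DeltaSampleSet("A", "observed", {1: np.array([0, 1, 1, 2])})
        b = DeltaSampleSet("A", "simulated", {1: np.array([0, 1, 1, 2])})
        pp = ws.pp_plot(a, b)
        _, fx, fy = pp.coords[1]
        assert fx.tolist() == fy.tolist()
        assert pp.max_deviation[1] == 0.0

    def test_hand_computed_coordinates(self):
        obs = DeltaSampleSet("A", "observed", {1: np.array([0, 0, 1])})
        sim = DeltaSampleSet("A", "simulated", {1: np.array([0, 1, 1])})
        pp = ws.pp_plot(obs, sim)
        delta, fx, fy = pp.coords[1]
        assert delta.tolist() == [0, 1]
        assert fx.tolist() == pytest.approx([1 / 3, 1.0])
        assert fy.tolist() == pytest.approx([2 / 3, 1.0])
        assert pp.max_deviation[1] == pytest.approx(1 / 3)

    def test_lower_variance_vertical_axis_signature(self):
        # equal medians, observed (vertical) has less spread: coordinates sit
        # below the identity left of the median and above it to the right
        rng = np.random.default_rng(4)
        narrow = rng.integers(-1, 2, size=4000)  # on {-1, 0, 1}
        wide = rng.integers(-3, 4, size=4000)  # on {-3..3}
        pp = ws.pp_plot(
            DeltaSampleSet("A", "observed", {1: narrow}),
            DeltaSampleSet("A", "simulated", {1: wide}),
        )
        delta, fx, fy = pp.coords[1]
        left = delta < 0
        right = (delta >= 0) & (delta < 3)
        assert (fy[left] < fx[left]).all()
        assert (fy[right] > fx[right]).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        obs = rng.integers(-3, 4, size=50)
        sim = rng.integers(-3, 4, size=80)
        p1 = ws.pp_plot(
            DeltaSampleSet("A", "observed", {1: obs}),
            DeltaSampleSet("A", "simulated", {1: sim}),
        )
        p2 = ws.pp_plot(
            DeltaSampleSet("A", "observed", {1: rng.permutation(obs)}),
            DeltaSampleSet("A", "simulated", {1: rng.permutation(sim)}),
        )
        assert p1.max_deviation[1] == p2.max_deviation[1]

    def test_concentrated_pmf_halves_variance(self):
        pmf = ws.EmpiricalPmf.geometric(0.3, 60)
        shrunk = ws.concentrated_pmf(pmf, weight=0.5)
        assert shrunk.var() / pmf.var() == pytest.approx(0.5, abs=0.02)
        assert shrunk.mean() == pytest.approx(pmf.mean(), abs=0.5)


def deterministic_scenario():
    """Electives only, point-mass LOS: the whole system is deterministic."""
    return GroundTruthConfig.build(
        wards=["A"],
        emergency_rates={"A": 0.0},
        wlos_spec={"A": {"elective": {"pmf": {3: 1.0}},
                         "emergency": {"pmf": {3: 1.0}}}},
        transitions={},
        electives={"A": (1,) * 7},
        horizon_days=10 * 7,
    )


class TestWindowedValidation:
    def test_initialisation_collapse_and_pool_sizes(self, small_hospital):
        cfg, stays = small_hospital
        params = cfg.to_parameters()
        run = run_validation_windows(params, stays, 0, h_max=6, n_reps=8, seed=3,
                                     max_windows=5)
        census = run.census
        for t0, res in zip(run.init_days, run.results):
            for wi, w in enumerate(params.wards):
                assert (res.ward_totals()[:, wi, 0] == census.series(w)[t0]).all()
        sims = ws.simulated_deltas(params, stays, run=run)
        for w in params.wards:
            for h in range(1, 7):
                assert len(sims[w].deltas[h]) == len(run.init_days) * 8

    def test_degenerate_model_reproduces_observed_deltas(self):
        cfg = deterministic_scenario()
        stays = ws.generate_records(cfg, seed=1)
        params = cfg.to_parameters()
        run = run_validation_windows(params, stays, 0, 6, n_reps=3, seed=0,
                                     census=ws.derive_census(stays, wards=["A"],
                                                             start=MON, end=day(70)))
        census = run.census
        sims = ws.simulated_deltas(params, stays, run=run)
        series = census.series("A")
        for h in range(1, 7):
            expected = sorted({series[t0] - series[t0 + h] for t0 in run.init_days})
            assert sorted(set(sims["A"].deltas[h].tolist())) == expected
            assert np.ptp(sims["A"].deltas[h].reshape(len(run.init_days), 3), axis=1).max() == 0

    def test_deterministic_coverage_is_one(self):
        cfg = deterministic_scenario()
        stays = ws.generate_records(cfg, seed=1)
        params = cfg.to_parameters()
        table = ws.interval_coverage(params, stays, 0, 6, n_reps=3, seed=0,
                                     census=ws.derive_census(stays, wards=["A"],
                                                             start=MON, end=day(70)))
        assert (table["coverage"] == 1.0).all()


class TestCompareWeekdayMeans:
    def test_simulation_of_itself_is_inside(self):
        rng = np.random.default_rng(6)
        series = rng.integers(5, 15, size=28)
        census = census_from_series(series)
        counts = np.stack([census.counts, census.counts])  # two identical reps
        res = SimulationResult(["A"], MON, counts, base_seed=0)
        table = ws.compare_weekday_means(census, res)
        assert table["inside"].all()

    def test_level_difference_flags_false(self):
        census = census_from_series([5] * 28)
        sim_counts = np.zeros((2, 1, 28, 2), dtype=int)
        sim_counts[:, 0, :, 0] = 9
        res = SimulationResult(["A"], MON, sim_counts, base_seed=0)
        table = ws.compare_weekday_means(census, res)
        assert not table[table["admission_type"] == "emergency"]["inside"].any()

    def test_correctly_specified_model_mostly_inside(self, small_hospital):
        """About 90% of weekday x type cells fall inside the 90% band when
        the model is the generator itself; cells within one observed
        trajectory are correlated, so the rate is pooled over several
        independently generated trajectories."""
        cfg, _ = small_hospital
        res = ws.simulate(cfg.to_parameters(),
                          schedule=cfg.weekly_schedule(0, cfg.horizon_days - 1),
                          horizon=cfg.horizon_days, n_reps=40, seed=14)
        band = SimulationResult(res.wards, res.start_date + dt.timedelta(days=28),
                                res.counts[:, :, 28:], 0)
        rates = []
        for seed in range(8):
            stays = ws.generate_records(cfg, seed=600 + seed)
            census = ws.derive_census(stays, wards=cfg.wards, start=MON,
                                      end=day(cfg.horizon_days))
            table = ws.compare_weekday_means(census.slice_days(28), band)
            rates.append(table["inside"].mean())
        assert np.mean(rates) >= 0.70


class TestPlots:
    def test_plot_files_written(self, tmp_path, small_hospital):
        cfg, stays = small_hospital
        params = cfg.to_parameters()
        run = run_validation_windows(params, stays, 0, 6, n_reps=5, seed=1, max_windows=4)
        sims = ws.simulated_deltas(params, stays, run=run)
        pps = {
            w: ws.pp_plot(ws.observed_deltas(run.census, w, 6), sims[w])
            for w in params.wards
        }
        from wardsim.validation import plot_fan_chart, plot_pp_grid

        plot_pp_grid(pps, tmp_path / "pp.png")
        plot_fan_chart(run, params.wards[0], tmp_path / "fan.png")
        assert (tmp_path / "pp.png").stat().st_size > 0
        assert (tmp_path / "fan.png").stat().st_size > 0
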