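import datetime as dt
import itertools

import numpy as np
import pytest

import wardsim as ws
from wardsim.engine import ElectiveSchedule, ScheduleEntry, SimulationError, sample_pmf
from wardsim.estimation import EmpiricalPmf, HospitalParameters

from conftest import MON, day


def single_ward_params(arrival_pmf, wlos_pmf, nonattendance=0.0):
    return HospitalParameters(
        wards=["A"],
        arrivals={("A", wd): arrival_pmf for wd in range(7)},
        wlos={("A", t, wd): wlos_pmf for t in ("emergency", "elective") for wd in range(7)},
        transitions={
            "emergency": np.array([[0.0, 1.0]]),
            "elective": np.array([[0.0, 1.0]]),
        },
        nonattendance_prob=nonattendance,
    )


ZERO = EmpiricalPmf.point_mass(0)


class TestSamplePmf:
    def test_point_mass(self):
        assert sample_pmf(EmpiricalPmf.point_mass(4), 0.0) == 4
        assert sample_pmf(EmpiricalPmf.point_mass(4), 0.999) == 4

    def test_inverse_cdf_boundary(self):
        pmf = EmpiricalPmf((1, 3), (0.5, 0.5))
        assert sample_pmf(pmf, 0.49) == 1
        assert sample_pmf(pmf, 0.51) == 3

    def test_empirical_frequencies(self):
        pmf = EmpiricalPmf((0, 2, 5), (0.2, 0.5, 0.3))
        rng = np.random.default_rng(8)
        u = rng.random(1_000_000)
        cdf = pmf.cdf()
        draws = np.asarray(pmf.support)[np.searchsorted(cdf, u, side="right")]
        for x, p in zip(pmf.support, pmf.probabilities):
            assert (draws == x).mean() == pytest.approx(p, abs=0.003)


class TestSimulate:
    def test_empty_system_stays_empty(self):
        params = single_ward_params(ZERO, EmpiricalPmf.point_mass(3))
        res = ws.simulate(params, horizon=10, n_reps=5, seed=1)
        assert res.counts.sum() == 0

    def test_deterministic_single_elective(self):
        params = single_ward_params(ZERO, EmpiricalPmf.point_mass(3))
        schedule = ElectiveSchedule([ScheduleEntry(0, "A", 1)], horizon=6)
        res = ws.simulate(params, schedule=schedule, horizon=6, n_reps=4, seed=1)
        for r in range(4):
            assert res.ward_totals()[r, 0].tolist() == [1, 1, 1, 0, 0, 0]

    def test_patient_conservation_deterministic(self):
        # 2 admissions/day, LOS exactly 3, no transfers: census is the sum
        # of the last three days' admissions and the day ledger balances
        params = single_ward_params(EmpiricalPmf.point_mass(2), EmpiricalPmf.point_mass(3))
        res = ws.simulate(params, horizon=10, n_reps=2, seed=0)
        assert res.ward_totals()[0, 0].tolist() == [2, 4, 6, 6, 6, 6, 6, 6, 6, 6]
        admissions = 2 * 10
        final_census = res.ward_totals()[0, 0, -1]
        discharges = admissions - final_census  # 3-night stays of days 0..6
        assert discharges == 2 * 7

    def test_unknown_schedule_ward_rejected_before_sampling(self):
        params = single_ward_params(ZERO, EmpiricalPmf.point_mass(3))
        schedule = ElectiveSchedule([ScheduleEntry(0, "X", 1)], horizon=6)
        with pytest.raises(SimulationError, match="X"):
            ws.simulate(params, schedule=schedule, horizon=6, n_reps=1, seed=1)

    def test_bit_reproducible(self, small_hospital):
        cfg, _ = small_hospital
        params = cfg.to_parameters()
        sched = cfg.weekly_schedule(0, 13)
        a = ws.simulate(params, schedule=sched, horizon=14, n_reps=20, seed=9)
        b = ws.simulate(params, schedule=sched, horizon=14, n_reps=20, seed=9)
        assert np.array_equal(a.counts, b.counts)
        c = ws.simulate(params, schedule=sched, horizon=14, n_reps=20, seed=10)
        assert not np.array_equal(a.counts, c.counts)

    def test_snapshot_day_zero_reproduced_exactly(self, small_hospital):
        cfg, _ = small_hospital
        snap = ws.generate_snapshot(cfg, warmup_days=100, seed=6)
        res = ws.simulate(cfg.to_parameters(), initial=snap, horizon=6, n_reps=15, seed=2)
        counts = snap.ward_counts()
        for wi, w in enumerate(res.wards):
            expected = sum(c for (ward, _), c in counts.items() if ward == w)
            assert (res.ward_totals()[:, wi, 0] == expected).all()

    def test_monotone_in_electives_under_crn(self, small_hospital):
        cfg, _ = small_hospital
        params = cfg.to_parameters()
        base = ElectiveSchedule([ScheduleEntry(2, "SUR", 2)], horizon=7)
        more = ElectiveSchedule(
            [ScheduleEntry(2, "SUR", 2), ScheduleEntry(3, "MED", 2)], horizon=7
        )
        a = ws.simulate(params, schedule=base, horizon=8, n_reps=10, seed=4, crn=True)
        b = ws.simulate(params, schedule=more, horizon=8, n_reps=10, seed=4, crn=True)
        total_a = a.counts.sum(axis=(1, 3))
        total_b = b.counts.sum(axis=(1, 3))
        assert (total_b >= total_a).all()
        assert (total_b[:, :3] == total_a[:, :3]).all()  # nothing before day 3 changes

    def test_crn_mode_matches_seeded_determinism(self, small_hospital):
        cfg, _ = small_hospital
        params = cfg.to_parameters()
        a = ws.simulate(params, horizon=10, n_reps=5, seed=3, crn=True)
        b = ws.simulate(params, horizon=10, n_reps=5, seed=3, crn=True)
        assert np.array_equal(a.counts, b.counts)

    def test_nonattendance_thins_electives(self):
        params = single_ward_params(ZERO, EmpiricalPmf.point_mass(1), nonattendance=0.3)
        schedule = ElectiveSchedule([ScheduleEntry(0, "A", 1)], horizon=1)
        res = ws.simulate(params, schedule=schedule, horizon=1, n_reps=4000, seed=5)
        attended = res.ward_totals()[:, 0, 0]
        assert attended.mean() == pytest.approx(0.7, abs=3 * np.sqrt(0.21 / 4000))


class TestEnumerationOracle:
    """Two-ward system with tiny supports vs exhaustive enumeration."""

    def _params(self):
        return HospitalParameters(
            wards=["A", "B"],
            arrivals={
                **{("A", wd): EmpiricalPmf((0, 1), (0.5, 0.5)) for wd in range(7)},
                **{("B", wd): EmpiricalPmf.point_mass(0) for wd in range(7)},
            },
            wlos={
                (w, t, wd): EmpiricalPmf((1, 2), (0.6, 0.4))
                for w in ("A", "B")
                for t in ("emergency", "elective")
                for wd in range(7)
            },
            transitions={
                "emergency": np.array([[0.0, 0.5, 0.5], [0.0, 0.0, 1.0]]),
                "elective": np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]),
            },
        )

    def _exact_day1_distribution(self):
        """Exhaustive enumeration of the (A, B) census at day 1."""
        dist: dict[tuple[int, int], float] = {}
        # day-0 arrival at A (n0), its LOS, its destination if it ends day 1,
        # day-1 arrival (n1); LOS of the day-1 arrival does not matter for day 1
        for n0, p_n0 in ((0, 0.5), (1, 0.5)):
            for n1, p_n1 in ((0, 0.5), (1, 0.5)):
                if n0 == 0:
                    key = (n1, 0)
                    dist[key] = dist.get(key, 0.0) + p_n0 * p_n1
                    continue
                for t0, p_t0 in ((1, 0.6), (2, 0.4)):
                    if t0 == 2:  # still on A at day 1
                        key = (n1 + 1, 0)
                        dist[key] = dist.get(key, 0.0) + p_n0 * p_n1 * p_t0
                    else:  # ends at day 1: transfer to B or discharge
                        for to_b, p_d in ((1, 0.5), (0, 0.5)):
                            key = (n1, to_b)
                            dist[key] = dist.get(key, 0.0) + p_n0 * p_n1 * p_t0 * p_d
        return dist

    def test_day1_census_distribution(self):
        exact = self._exact_day1_distribution()
        assert sum(exact.values()) == pytest.approx(1.0)
        n = 40_000
        res = ws.simulate(self._params(), horizon=2, n_reps=n, seed=13)
        tot = res.ward_totals()
        for (a, b), p in exact.items():
            freq = ((tot[:, 0, 1] == a) & (tot[:, 1, 1] == b)).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert freq == pytest.approx(p, abs=max(4 * se, 1e-3))


class TestSchedule:
    def test_csv_round_trip_with_known_los(self, tmp_path):
        sched = ElectiveSchedule(
            [ScheduleEntry(1, "A", 2, (3, 5)), ScheduleEntry(2, "B", 1)], horizon=6
        )
        path = tmp_path / "schedule.csv"
        sched.to_csv(path)
        back = ElectiveSchedule.from_csv(path, horizon=6)
        assert sorted(back.entries, key=lambda e: e.day) == sorted(
            sched.entries, key=lambda e: e.day
        )

    def test_known_los_length_checked(self):
        with pytest.raises(SimulationError):
            ScheduleEntry(0, "A", 2, (3,))

    def test_summary_frame_shape(self, small_hospital):
        cfg, _ = small_hospital
        res = ws.simulate(cfg.to_parameters(), horizon=5, n_reps=8, seed=0)
        frame = res.summary_frame()
        assert len(frame) == len(cfg.wards) * 5
        assert (frame["lo"] <= frame["hi"]).all()
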