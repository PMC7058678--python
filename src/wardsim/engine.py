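"""Discrete-time, infinite-server, multi-ward stochastic simulation.

The model advances in one-day steps.  Each day, every ward receives a
random number of emergency admissions drawn from its (ward, weekday)
empirical count distribution, plus the elective admissions planned in the
schedule (thinned by an independent non-attendance probability).  Every
admission draws a ward length of stay (WLOS, in midnights, minimum one)
from the (ward, admission type, arrival weekday) pmf.  When a stay ends the
patient is either discharged or transferred according to the admission-type
transition matrix; a transfer starts a new stay at the destination ward
with a fresh WLOS conditional on the new ward and the transfer-day weekday,
and the patient occupies only the destination ward at that midnight.

There is no capacity constraint anywhere in the dynamics (infinite-server
assumption): ward capacities enter only in reporting, where they define
exceedance probabilities.  This keeps the model simple and is well suited
to estimating the probability of demand exceeding a given level.

When a :class:`~wardsim.state.SystemSnapshot` is supplied, day 0 of the
output is the capture midnight: the snapshot residents occupy their wards
exactly at day 0 and their remaining stays are drawn from the conditional
distributions of :mod:`wardsim.state` (conditioned on having been present
at the capture midnight, i.e. on ``T >= s + 1``), so the simulated
trajectory "collapses" onto the observed census at every re-initialisation
point.  New arrivals are then generated from day 1 onwards.

Randomness: by default each replication uses one stream seeded from
``(seed, replication)``.  In common-random-number (CRN) mode every entity
(arrival-count cell, emergency patient, elective slot, resident) gets its
own deterministically keyed stream, so schedule variants that differ only
in a few elective slots share every other random outcome pathwise.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import DISCHARGE, EmpiricalPmf, HospitalParameters
from .records import ADMISSION_TYPES, CensusTrajectory
from .state import ConditionalCdf, SystemSnapshot, conditional_cdf

#: default replication counts: validation runs vs decision-support runs
DEFAULT_REPS_VALIDATION = 100
DEFAULT_REPS_DECISION = 400

_DEFAULT_START = dt.date(2024, 1, 1)  # a Monday


class SimulationError(ValueError):
    """Raised for inconsistent simulation inputs."""


def sample_pmf(pmf: EmpiricalPmf, u: float) -> int:
    """Inverse-transform sample: smallest support value x with CDF(x) > u."""
    cdf = pmf.cdf()
    i = min(int(np.searchsorted(cdf, u, side="right")), len(cdf) - 1)
    return int(pmf.support[i])


@dataclass(frozen=True)
class ScheduleEntry:
    """Planned elective admissions: ``count`` patients to ``ward`` on ``day``.

    ``known_los`` optionally carries the clinicians' length-of-stay
    estimates (one per patient) used by the estimated-discharge-information
    mechanism; it must have exactly ``count`` entries when present.
    """

    day: int
    ward: str
    count: int
    known_los: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.day < 0 or self.count < 0:
            raise SimulationError("schedule day and count must be non-negative")
        if self.known_los is not None and len(self.known_los) != self.count:
            raise SimulationError("known_los must list one LOS per planned patient")


@dataclass
class ElectiveSchedule:
    """The elective admissions over a planning horizon (the decision variables)."""

    entries: list[ScheduleEntry] = field(default_factory=list)
    horizon: int = 7

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.day >= self.horizon + 1:
                raise SimulationError(
                    f"schedule entry on day {e.day} outside horizon {self.horizon}"
                )

    def total_planned(self) -> int:
        return sum(e.count for e in self.entries)

    def wards(self) -> set[str]:
        return {e.ward for e in self.entries}

    def to_csv(self, path) -> None:
        """CSV columns day, ward, count plus an optional semicolon-separated
        known_los column carrying per-patient LOS estimates."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["day", "ward", "count", "known_los"])
            for e in sorted(self.entries, key=lambda e: (e.day, e.ward)):
                los = "" if e.known_los is None else ";".join(map(str, e.known_los))
                writer.writerow([e.day, e.ward, e.count, los])

    @classmethod
    def from_csv(cls, path, horizon: int | None = None) -> "ElectiveSchedule":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                los_text = (row.get("known_los") or "").strip()
                entries.append(
                    ScheduleEntry(
                        int(row["day"]),
                        row["ward"],
                        int(row["count"]),
                        tuple(int(x) for x in los_text.split(";")) if los_text else None,
                    )
                )
        h = horizon if horizon is not None else max((e.day for e in entries), default=6)
        return cls(entries, h)


@dataclass
class SimulationResult:
    """Replicated midnight-census trajectories.

    ``counts`` has shape ``(n_reps, n_wards, n_days, 2)``; the last axis is
    (emergency, elective).  ``initialised`` records whether day 0 is a
    snapshot capture midnight (excluded from decision-support reporting).
    """

    wards: list[str]
    start_date: dt.date
    counts: np.ndarray
    base_seed: int
    initialised: bool = False

    @property
    def n_reps(self) -> int:
        return self.counts.shape[0]

    @property
    def n_days(self) -> int:
        return self.counts.shape[2]

    def weekdays(self) -> np.ndarray:
        return (self.start_date.weekday() + np.arange(self.n_days)) % 7

    def replication(self, i: int) -> CensusTrajectory:
        return CensusTrajectory(list(self.wards), self.start_date, self.counts[i])

    def ward_totals(self) -> np.ndarray:
        """Occupancy summed over admission types: shape (n_reps, n_wards, n_days)."""
        return self.counts.sum(axis=3)

    def mean_census(self) -> np.ndarray:
        """Mean over replications: shape (n_wards, n_days, 2)."""
        return self.counts.mean(axis=0)

    def percentile_band(self, level: float = 0.90) -> tuple[np.ndarray, np.ndarray]:
        """Central prediction band per (ward, day), over type totals.

        Uses linearly interpolated empirical percentiles of the replication
        sample, e.g. the 5th/95th for a 90% band.
        """
        lo = 100 * (1 - level) / 2
        tot = self.ward_totals()
        return (
            np.percentile(tot, lo, axis=0),
            np.percentile(tot, 100 - lo, axis=0),
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        dates = [self.start_date + dt.timedelta(days=j) for j in range(self.n_days)]
        for r in range(self.n_reps):
            for i, w in enumerate(self.wards):
                for j, d in enumerate(dates):
                    for k, t in enumerate(ADMISSION_TYPES):
                        rows.append((r, w, d.isoformat(), t, int(self.counts[r, i, j, k])))
        return pd.DataFrame(
            rows, columns=["replication", "ward", "date", "admission_type", "count"]
        )

    def summary_frame(self, level: float = 0.90) -> pd.DataFrame:
        lo, hi = self.percentile_band(level)
        mean = self.ward_totals().mean(axis=0)
        rows = []
        dates = [self.start_date + dt.timedelta(days=j) for j in range(self.n_days)]
        for i, w in enumerate(self.wards):
            for j, d in enumerate(dates):
                rows.append((w, d.isoformat(), mean[i, j], lo[i, j], hi[i, j]))
        return pd.DataFrame(rows, columns=["ward", "date", "mean", "lo", "hi"])


# ---------------------------------------------------------------------------
# internal precomputation
# ---------------------------------------------------------------------------

# stream tags for CRN keying
_S_ARRIVAL_COUNT, _S_EMERGENCY, _S_ELECTIVE, _S_RESIDENT = 1, 2, 3, 4


class _Prepared:
    """Arrays and caches derived once per simulate() call."""

    def __init__(self, params: HospitalParameters):
        self.params = params
        self.wards = params.wards
        self.widx = {w: i for i, w in enumerate(self.wards)}
        self.arrival = {}
        for i, w in enumerate(self.wards):
            for wd in range(7):
                pmf = params.arrival_pmf(w, wd)
                self.arrival[(i, wd)] = (np.asarray(pmf.support), pmf.cdf())
        self.wlos = {}
        for i, w in enumerate(self.wards):
            for k, t in enumerate(ADMISSION_TYPES):
                for wd in range(7):
                    pmf = params.wlos_pmf(w, t, wd)
                    self.wlos[(i, k, wd)] = (np.asarray(pmf.support), pmf.cdf())
        self.trans_cum = {
            k: np.cumsum(params.transitions[t], axis=1)
            for k, t in enumerate(ADMISSION_TYPES)
        }
        self._cond: dict[tuple[int, int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def draw(self, table: tuple[np.ndarray, np.ndarray], u: float) -> int:
        support, cdf = table
        i = min(int(np.searchsorted(cdf, u, side="right")), len(cdf) - 1)
        return int(support[i])

    def residual(self, wi: int, ti: int, wd: int, elapsed: int):
        """Residual-LOS table for a resident, conditioned on presence.

        Presence at the capture midnight implies T >= elapsed + 1, so the
        conditional distribution is evaluated at ``elapsed + 1``; the draw
        is the number of midnights from the capture midnight onwards
        (>= 1, counting the capture midnight itself).
        """
        key = (wi, ti, wd, elapsed)
        if key not in self._cond:
            pmf = self.params.wlos_pmf(self.wards[wi], ADMISSION_TYPES[ti], wd)
            cond = conditional_cdf(pmf, elapsed + 1)
            self._cond[key] = (np.asarray(cond.pmf.support) + 1, cond.pmf.cdf())
        return self._cond[key]


def _chain(
    prep: _Prepared,
    counts: np.ndarray,
    wi: int,
    ti: int,
    day: int,
    nights: int,
    rng: np.random.Generator,
    n_days: int,
) -> None:
    """Occupy wards along a patient's transfer chain until discharge/horizon."""
    n_wards = len(prep.wards)
    start_wd = prep._start_weekday
    while True:
        a, b = day, day + nights
        if a < n_days:
            counts[wi, a:min(b, n_days), ti] += 1
        day = b
        if day >= n_days:
            return
        dest = int(np.searchsorted(prep.trans_cum[ti][wi], rng.random(), side="right"))
        if dest >= n_wards:  # discharge
            return
        wi = dest
        wd = (start_wd + day) % 7
        nights = max(1, prep.draw(prep.wlos[(wi, ti, wd)], rng.random()))


def simulate(
    params: HospitalParameters,
    schedule: ElectiveSchedule | None = None,
    initial: SystemSnapshot | None = None,
    horizon: int = 7,
    n_reps: int = DEFAULT_REPS_VALIDATION,
    seed: int | Sequence[int] = 0,
    start_date: dt.date | None = None,
    d: float | None = None,
    crn: bool = False,
) -> SimulationResult:
    """Run the infinite-server ward-network simulation.

    With ``initial`` supplied the result covers days ``0..horizon`` where
    day 0 is the capture midnight (the snapshot reproduced exactly) and new
    arrivals begin on day 1; without it the result covers days
    ``0..horizon-1`` starting from an empty hospital with arrivals on day 0.

    ``d`` activates the estimated-discharge-information mechanism: each
    snapshot resident and each scheduled elective carrying a true length of
    stay uses it with probability ``d`` (an independent Bernoulli per
    patient per replication) and otherwise samples from the applicable
    empirical distribution.  Emergency arrivals during the horizon never
    have truth available.
    """
    if horizon < 1:
        raise SimulationError("horizon must be >= 1")
    if schedule is not None:
        unknown = schedule.wards() - set(params.wards)
        if unknown:
            raise SimulationError(f"schedule references unknown wards: {sorted(unknown)}")
    if d is not None:
        if not 0 <= d <= 1:
            raise SimulationError("d must be in [0, 1]")
        if d > 0:
            missing = [
                r.patient_id
                for r in (initial.residents if initial else [])
                if r.known_remaining is None
            ]
            if schedule is not None:
                missing += [
                    f"elective(day={e.day},ward={e.ward})"
                    for e in schedule.entries
                    if e.count > 0 and e.known_los is None
                ]
            if missing:
                raise SimulationError(
                    "d > 0 requires true LOS for every resident and scheduled "
                    f"elective; missing for: {missing}"
                )

    prep = _Prepared(params)
    if initial is not None:
        start_date = initial.capture_date
        n_days = horizon + 1
        first_arrival_day = 1
        for r in initial.residents:
            if r.ward not in prep.widx:
                raise SimulationError(f"snapshot references unknown ward {r.ward!r}")
    else:
        start_date = start_date or _DEFAULT_START
        n_days = horizon
        first_arrival_day = 0
    start_wd = start_date.weekday()
    prep._start_weekday = start_wd

    sched_by_day: dict[int, list[ScheduleEntry]] = {}
    if schedule is not None:
        for e in sorted(schedule.entries, key=lambda e: (e.day, e.ward)):
            if e.day < first_arrival_day:
                continue  # the snapshot already reflects the initiation day
            sched_by_day.setdefault(e.day, []).append(e)

    q = params.nonattendance_prob
    n_wards = len(prep.wards)
    counts = np.zeros((n_reps, n_wards, n_days, 2), dtype=np.int64)
    e_idx = ADMISSION_TYPES.index("emergency")
    seed_key = list(seed) if isinstance(seed, (list, tuple)) else [seed]

    for rep in range(n_reps):
        rep_rng = np.random.default_rng([*seed_key, rep])

        def entity_rng(*key: int) -> np.random.Generator:
            return np.random.default_rng([*seed_key, rep, *key]) if crn else rep_rng

        c = counts[rep]
        # snapshot residents
        if initial is not None:
            for ridx, r in enumerate(initial.residents):
                rng = entity_rng(_S_RESIDENT, ridx)
                wi = prep.widx[r.ward]
                ti = ADMISSION_TYPES.index(r.admission_type)
                use_truth = (
                    d is not None
                    and r.known_remaining is not None
                    and rng.random() < d
                )
                if use_truth:
                    nights = r.known_remaining
                else:
                    nights = prep.draw(
                        prep.residual(wi, ti, r.arrival_weekday, r.elapsed),
                        rng.random(),
                    )
                _chain(prep, c, wi, ti, 0, nights, rng, n_days)
        # daily arrivals
        for day in range(first_arrival_day, n_days):
            wd = (start_wd + day) % 7
            for wi in range(n_wards):
                n_emerg = prep.draw(
                    prep.arrival[(wi, wd)],
                    entity_rng(_S_ARRIVAL_COUNT, day, wi).random(),
                )
                for i in range(n_emerg):
                    rng = entity_rng(_S_EMERGENCY, day, wi, i)
                    nights = max(1, prep.draw(prep.wlos[(wi, e_idx, wd)], rng.random()))
                    _chain(prep, c, wi, e_idx, day, nights, rng, n_days)
            for entry in sched_by_day.get(day, ()):
                wi = prep.widx[entry.ward]
                for slot in range(entry.count):
                    rng = entity_rng(_S_ELECTIVE, day, wi, slot)
                    if q > 0 and rng.random() < q:
                        continue  # non-attendance
                    use_truth = (
                        d is not None
                        and entry.known_los is not None
                        and rng.random() < d
                    )
                    if use_truth:
                        nights = max(1, entry.known_los[slot])
                    else:
                        nights = max(1, prep.draw(prep.wlos[(wi, 1, wd)], rng.random()))
                    _chain(prep, c, wi, 1, day, nights, rng, n_days)

    return SimulationResult(
        wards=list(prep.wards),
        start_date=start_date,
        counts=counts,
        base_seed=seed_key[0],
        initialised=initial is not None,
    )
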