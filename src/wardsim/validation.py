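"""The delta-method: distributional validation of a symbiotic simulation.

A symbiotic simulation is re-initialised from the physical system, so the
distribution of its output is a function of the elapsed time ``h`` since
initialisation.  The delta-method pools the observed h-step occupancy
changes

    delta_{t,h} = M_t - M_{t+h}          (h = 1..H over all observed days)

and compares them, per ward and per ``h``, with the simulated changes
``M_{t0} - Mhat_{t0+h}`` pooled over every initiation point ``t0`` (the
chosen weekday of each week) and every replication.  Because ``M_{t0}``
takes the same value in the simulation and in the physical system, any
difference in trend, variability or cycling shows up as a departure of the
P-P plot of the two empirical distributions from the identity line.  The
maximum absolute deviation from the identity is reported as a numeric
summary; it is an extension for convenience, not a test statistic with a
null distribution — the method itself is a visual/distributional check.

Two further checks are provided: prediction-interval coverage (the fraction
of observed midnight censuses inside their central simulation interval,
pooled over non-initiation days) and the black-box weekday-mean comparison
used to validate the underlying non-symbiotic model.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ElectiveSchedule, ScheduleEntry, SimulationResult, simulate
from .estimation import EmpiricalPmf, HospitalParameters, apply_aggregation
from .records import ADMISSION_TYPES, CensusTrajectory, WardStay, derive_census
from .state import SystemSnapshot, capture_snapshot

DEFAULT_HORIZON = 6  # Monday initialisation, six-day planning horizon


class ValidationError(ValueError):
    """Raised for inputs the delta-method cannot be applied to."""


@dataclass
class DeltaSampleSet:
    """Multisets of h-step occupancy changes for one ward.

    ``deltas[h]`` holds every observed (or simulated) value of
    ``M_t - M_{t+h}``; for an N-day observed series there are N - h of
    them, for a simulated set (#initiation points) x (#replications).
    """

    ward: str
    source: str  # "observed" | "simulated"
    deltas: dict[int, np.ndarray]

    def horizons(self) -> list[int]:
        return sorted(self.deltas)


def observed_deltas(census: CensusTrajectory, ward: str, h_max: int) -> DeltaSampleSet:
    """All observed delta_{t,h} = M_t - M_{t+h} for h = 1..h_max."""
    series = census.series(ward)
    n = len(series)
    if h_max >= n:
        raise ValidationError(f"horizon {h_max} >= series length {n}")
    return DeltaSampleSet(
        ward,
        "observed",
        {h: (series[: n - h] - series[h:]).astype(np.int64) for h in range(1, h_max + 1)},
    )


# ---------------------------------------------------------------------------
# windowed re-initialised simulation
# ---------------------------------------------------------------------------


@dataclass
class ValidationRun:
    """One sweep of weekly re-initialised simulations over a record set."""

    census: CensusTrajectory  # observed, aggregated to the modelled wards
    init_days: list[int]  # day indices of the initiation points
    results: list[SimulationResult]  # one per initiation point
    h_max: int


def _schedule_from_records(
    stays: Sequence[WardStay],
    t0_date: dt.date,
    h_max: int,
    wards: Sequence[str],
) -> ElectiveSchedule:
    """The observed elective admissions in (t0, t0 + h_max] as a schedule."""
    counts: dict[tuple[int, str], int] = {}
    for s in stays:
        if s.admission_type != "elective" or s.arrival_date != s.hospital_admission_date:
            continue
        offset = (s.arrival_date - t0_date).days
        if 1 <= offset <= h_max and s.ward in wards:
            counts[(offset, s.ward)] = counts.get((offset, s.ward), 0) + 1
    return ElectiveSchedule(
        [ScheduleEntry(day, w, c) for (day, w), c in sorted(counts.items())], h_max
    )


def run_validation_windows(
    params: HospitalParameters,
    stays: Sequence[WardStay],
    init_weekday: int = 0,
    h_max: int = DEFAULT_HORIZON,
    n_reps: int = 100,
    seed: int = 0,
    census: CensusTrajectory | None = None,
    max_windows: int | None = None,
) -> ValidationRun:
    """Re-initialise weekly and simulate each planning horizon.

    For every initiation date of the chosen weekday a snapshot is captured
    from the records, the observed elective admissions of the following
    ``h_max`` days are replayed as the schedule, and the symbiotic
    simulation is run for ``n_reps`` replications.  Each window derives its
    replication streams from ``(seed, window index)``.
    """
    mapped = apply_aggregation(stays, params.aggregation) if params.aggregation else list(stays)
    if census is None:
        census = derive_census(mapped, wards=params.wards)
    n_days = census.n_days
    init_days = [
        t for t, wd in enumerate(census.weekdays()) if wd == init_weekday and t + h_max < n_days
    ]
    if max_windows is not None:
        if len(init_days) > max_windows:
            # spread the windows over the whole record span
            pick = np.linspace(0, len(init_days) - 1, max_windows).round().astype(int)
            init_days = [init_days[i] for i in sorted(set(pick.tolist()))]
    if len(init_days) < 2:
        raise ValidationError("records must span at least two initiation weeks")
    results = []
    for k, t0 in enumerate(init_days):
        t0_date = census.start_date + dt.timedelta(days=t0)
        snapshot = capture_snapshot(mapped, t0_date)
        schedule = _schedule_from_records(mapped, t0_date, h_max, params.wards)
        results.append(
            simulate(
                params,
                schedule=schedule,
                initial=snapshot,
                horizon=h_max,
                n_reps=n_reps,
                seed=(seed, k),
            )
        )
    return ValidationRun(census, init_days, results, h_max)


def simulated_deltas(
    params: HospitalParameters,
    stays: Sequence[WardStay],
    init_weekday: int = 0,
    h_max: int = DEFAULT_HORIZON,
    n_reps: int = 100,
    seed: int = 0,
    run: ValidationRun | None = None,
    **kwargs,
) -> dict[str, DeltaSampleSet]:
    """Simulated delta pools per ward: M_{t0} - Mhat_{t0+h}.

    ``M_{t0}`` is the shared observed starting value, so the simulated and
    observed pools coincide exactly at h = 0 (the collapse property).
    """
    if run is None:
        run = run_validation_windows(
            params, stays, init_weekday, h_max, n_reps, seed, **kwargs
        )
    out: dict[str, DeltaSampleSet] = {}
    for wi, w in enumerate(params.wards):
        obs_series = run.census.series(w)
        pools: dict[int, list[np.ndarray]] = {h: [] for h in range(1, run.h_max + 1)}
        for t0, res in zip(run.init_days, run.results):
            m0 = obs_series[t0]
            sim = res.ward_totals()[:, wi, :]  # (reps, h_max + 1)
            for h in range(1, run.h_max + 1):
                pools[h].append(m0 - sim[:, h])
        out[w] = DeltaSampleSet(
            w, "simulated", {h: np.concatenate(v).astype(np.int64) for h, v in pools.items()}
        )
    return out


# ---------------------------------------------------------------------------
# P-P plot comparison
# ---------------------------------------------------------------------------


@dataclass
class PPPlotResult:
    """P-P coordinates of simulated vs observed delta distributions.

    For each horizon ``h`` the empirical CDFs are evaluated on the union of
    the two supports; ``coords[h]`` is ``(delta values, F_simulation,
    F_physical_system)``.  ``max_deviation[h]`` is the maximum absolute
    vertical distance from the identity line.
    """

    ward: str
    coords: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    max_deviation: dict[int, float]

    def overall_max_deviation(self) -> float:
        return max(self.max_deviation.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h, (delta, fx, fy) in sorted(self.coords.items()):
            for i in range(len(delta)):
                rows.append((self.ward, h, int(delta[i]), fx[i], fy[i]))
        return pd.DataFrame(
            rows, columns=["ward", "h", "delta", "F_simulation", "F_physical_system"]
        )


def _ecdf(sample: np.ndarray, points: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(sample), points, side="right") / len(sample)


def pp_plot(observed: DeltaSampleSet, simulated: DeltaSampleSet) -> PPPlotResult:
    """P-P coordinates (F_simulation, F_physical_system) per horizon."""
    coords = {}
    max_dev = {}
    for h in observed.horizons():
        obs, sim = observed.deltas[h], simulated.deltas[h]
        if len(obs) == 0 or len(sim) == 0:
            raise ValidationError(f"empty delta sample at h={h}")
        support = np.union1d(obs, sim)
        fx = _ecdf(sim, support)
        fy = _ecdf(obs, support)
        coords[h] = (support, fx, fy)
        max_dev[h] = float(np.abs(fy - fx).max())
    return PPPlotResult(observed.ward, coords, max_dev)


def concentrated_pmf(pmf: EmpiricalPmf, weight: float = 0.5) -> EmpiricalPmf:
    """Mix a pmf with a point mass at its (rounded) mean.

    Keeps the mean essentially unchanged while multiplying the variance by
    about ``1 - weight``; used to construct deliberately misspecified
    lower-variance length-of-stay models for power checks.
    """
    centre = int(round(pmf.mean()))
    table = {int(x): (1 - weight) * p for x, p in zip(pmf.support, pmf.probabilities)}
    table[centre] = table.get(centre, 0.0) + weight
    return EmpiricalPmf.from_dict(table, pmf.sample_size)


def misspecify_wlos(params: HospitalParameters, weight: float = 0.5) -> HospitalParameters:
    """A copy of ``params`` with every WLOS pmf concentrated toward its mean."""
    return HospitalParameters(
        wards=list(params.wards),
        arrivals=dict(params.arrivals),
        wlos={k: concentrated_pmf(pmf, weight) for k, pmf in params.wlos.items()},
        transitions={t: m.copy() for t, m in params.transitions.items()},
        nonattendance_prob=params.nonattendance_prob,
        aggregation=dict(params.aggregation),
    )


# ---------------------------------------------------------------------------
# prediction-interval coverage
# ---------------------------------------------------------------------------


def interval_coverage(
    params: HospitalParameters,
    stays: Sequence[WardStay],
    init_weekday: int = 0,
    h_max: int = DEFAULT_HORIZON,
    n_reps: int = 100,
    level: float = 0.90,
    seed: int = 0,
    run: ValidationRun | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fraction of observed censuses inside their central prediction interval.

    Intervals are linearly interpolated empirical percentiles across
    replications (5th/95th for a 90% level); observations equal to an
    interval endpoint count as covered.  Initiation days are excluded
    (their interval has zero width by construction).  Returns one row per
    ward plus a pooled ``"ALL"`` row.
    """
    if run is None:
        run = run_validation_windows(
            params, stays, init_weekday, h_max, n_reps, seed, **kwargs
        )
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    inside = {w: 0 for w in params.wards}
    total = {w: 0 for w in params.wards}
    for t0, res in zip(run.init_days, run.results):
        tot = res.ward_totals()  # (reps, wards, h_max+1)
        lo = np.percentile(tot, lo_q, axis=0)
        hi = np.percentile(tot, hi_q, axis=0)
        for wi, w in enumerate(params.wards):
            obs = run.census.series(w)[t0 + 1 : t0 + run.h_max + 1]
            ok = (obs >= lo[wi, 1:]) & (obs <= hi[wi, 1:])
            inside[w] += int(ok.sum())
            total[w] += len(obs)
    rows = [
        (w, inside[w] / total[w] if total[w] else np.nan, total[w]) for w in params.wards
    ]
    rows.append(("ALL", sum(inside.values()) / sum(total.values()), sum(total.values())))
    return pd.DataFrame(rows, columns=["ward", "coverage", "n_observations"])


# ---------------------------------------------------------------------------
# black-box weekday-mean comparison
# ---------------------------------------------------------------------------


def compare_weekday_means(
    observed: CensusTrajectory, result: SimulationResult, level: float = 0.90
) -> pd.DataFrame:
    """Observed weekday-mean occupancy vs the simulation's weekday-mean band.

    Hospital-wide totals per admission type.  The two-tailed interval is
    the central band of the per-replication weekday means (the 5th/95th
    empirical percentiles for a 90% level), so a correctly specified model
    contains the observed trajectory's weekday mean in about ``level`` of
    the cells; the flag marks whether it does (endpoints inclusive).
    """
    if observed.n_days < 7 or result.n_days < 7:
        raise ValidationError("both series must cover at least one full week")
    obs_wd = observed.weekdays()
    sim_wd = result.weekdays()
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    rows = []
    for k, t in enumerate(ADMISSION_TYPES):
        obs_tot = observed.counts[:, :, k].sum(axis=0)
        sim_tot = result.counts[:, :, :, k].sum(axis=1)  # (reps, days)
        for wd in range(7):
            obs_mean = float(obs_tot[obs_wd == wd].mean())
            per_rep = sim_tot[:, sim_wd == wd].mean(axis=1)
            sim_mean = float(per_rep.mean())
            lo = float(np.percentile(per_rep, lo_q))
            hi = float(np.percentile(per_rep, hi_q))
            rows.append((wd, t, obs_mean, sim_mean, lo, hi, bool(lo <= obs_mean <= hi)))
    return pd.DataFrame(
        rows,
        columns=[
            "weekday",
            "admission_type",
            "observed_mean",
            "simulated_mean",
            "ci_lo",
            "ci_hi",
            "inside",
        ],
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_pp_grid(results: Mapping[str, PPPlotResult], path) -> None:
    """One P-P panel per ward, horizons overlaid, identity line dashed."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    wards = list(results)
    fig, axes = plt.subplots(1, len(wards), figsize=(3.2 * len(wards), 3.2), squeeze=False)
    for ax, w in zip(axes[0], wards):
        for h, (_, fx, fy) in sorted(results[w].coords.items()):
            ax.plot(fx, fy, marker=".", ms=3, lw=0.8, label=f"h={h}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(w)
        ax.set_xlabel("F simulation")
        ax.set_ylabel("F physical system")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fan_chart(run: ValidationRun, ward: str, path, level: float = 0.90) -> None:
    """Observed census with the re-initialised prediction band per window."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    wi = run.census.ward_index(ward)
    series = run.census.series(ward)
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.plot(series, lw=1.2, color="k", label="observed")
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    for t0, res in zip(run.init_days, run.results):
        tot = res.ward_totals()[:, wi, :]
        days = np.arange(t0, t0 + run.h_max + 1)
        ax.plot(days, np.percentile(tot, lo_q, axis=0), "C0--", lw=0.8)
        ax.plot(days, np.percentile(tot, hi_q, axis=0), "C0--", lw=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel(f"midnight occupancy, {ward}")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
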