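"""Decision support: capacity early warning and the value of discharge estimates.

Two applications of the symbiotic simulation:

* **Early warning.**  For each ward and day of the planning horizon,
  the probability (over replications) that the midnight demand for beds
  exceeds the warning threshold (a fraction of capacity, default 90%) and
  the maximum capacity.  The headline scalar is BMOC — *bed-midnights over
  capacity* — the number of beds in excess of each ward's capacity summed
  over wards and midnights of the horizon, averaged over replications.
  Alternative elective schedules (postponements, cancellations) are
  compared under common random numbers so differences are attributable to
  the schedule alone.

* **Estimated discharge dates (EDD).**  A parameter ``d`` controls the
  proportion of correct length-of-stay estimates: each snapshot resident
  and scheduled elective uses their true (remaining) LOS with probability
  ``d`` and an empirical-distribution draw otherwise.  The response
  reported is the standard deviation of midnight occupancy across
  replications, per day, averaged by weekday — smaller is a more precise
  forecast.

The initiation day (day 0 of a snapshot-initialised run) is excluded from
probabilities and from BMOC: the state there is given, not predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import ElectiveSchedule, SimulationResult, simulate
from .estimation import HospitalParameters
from .state import SystemSnapshot


class DecisionError(ValueError):
    """Raised for inconsistent decision-support inputs."""


@dataclass
class CapacityConfig:
    """Per-ward maximum beds and the early-warning fraction."""

    capacities: dict[str, int]
    warning_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.warning_fraction <= 1:
            raise DecisionError("warning fraction must be in (0, 1]")
        for w, c in self.capacities.items():
            if int(c) < 1:
                raise DecisionError(f"capacity for ward {w!r} must be >= 1")
            self.capacities[w] = int(c)

    @classmethod
    def from_yaml(cls, path) -> "CapacityConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(dict(doc["capacities"]), float(doc.get("warning_fraction", 0.9)))


@dataclass
class WarningReport:
    """Exceedance probabilities per (ward, day) and the mean BMOC."""

    wards: list[str]
    days: list[int]  # day indices included in the probabilities
    p_threshold: np.ndarray  # P(occupancy > warning_fraction * capacity)
    p_capacity: np.ndarray  # P(occupancy > capacity)
    bmoc_per_replication: np.ndarray
    n_reps: int

    @property
    def bmoc(self) -> float:
        """Mean bed-midnights over capacity, over replications."""
        return float(self.bmoc_per_replication.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.wards):
            for j, day in enumerate(self.days):
                rows.append((w, day, self.p_threshold[i, j], self.p_capacity[i, j]))
        return pd.DataFrame(rows, columns=["ward", "day", "p_threshold", "p_capacity"])

    def summary(self) -> str:
        return f"BMOC = {self.bmoc:.2f} bed-midnights over capacity (mean of {self.n_reps} replications)"


def warning_report(result: SimulationResult, caps: CapacityConfig) -> WarningReport:
    """Exceedance probabilities and BMOC from replicated trajectories.

    Thresholds are strict: a day counts when occupancy is strictly above
    ``warning_fraction * capacity`` (real-valued) or strictly above the
    capacity.  For a snapshot-initialised result day 0 is excluded.
    """
    missing = [w for w in result.wards if w not in caps.capacities]
    if missing:
        raise DecisionError(f"no capacity configured for wards: {missing}")
    first = 1 if result.initialised else 0
    days = list(range(first, result.n_days))
    tot = result.ward_totals()[:, :, first:]  # (reps, wards, days)
    cap = np.array([caps.capacities[w] for w in result.wards], dtype=float)
    warn = caps.warning_fraction * cap
    p_thr = (tot > warn[None, :, None]).mean(axis=0)
    p_cap = (tot > cap[None, :, None]).mean(axis=0)
    over = np.clip(tot - cap[None, :, None], 0, None)
    bmoc_rep = over.sum(axis=(1, 2))
    return WarningReport(
        wards=list(result.wards),
        days=days,
        p_threshold=p_thr,
        p_capacity=p_cap,
        bmoc_per_replication=bmoc_rep,
        n_reps=result.n_reps,
    )


def compare_schedules(
    params: HospitalParameters,
    snapshot: SystemSnapshot,
    schedules: Mapping[str, ElectiveSchedule],
    caps: CapacityConfig,
    n_reps: int = 400,
    seed: int = 0,
    horizon: int | None = None,
) -> tuple[dict[str, WarningReport], pd.DataFrame]:
    """Evaluate named elective schedules under common random numbers.

    All schedules share the horizon and ward set; the first named schedule
    is the reference.  Returns the per-schedule reports and a delta table
    of capacity-exceedance probabilities and BMOC against the reference.
    """
    names = list(schedules)
    if not names:
        raise DecisionError("no schedules to compare")
    horizons = {schedules[n].horizon for n in names}
    if len(horizons) != 1:
        raise DecisionError(f"schedules have inconsistent horizons: {horizons}")
    h = horizon if horizon is not None else horizons.pop()
    reports = {}
    for name in names:
        res = simulate(
            params,
            schedule=schedules[name],
            initial=snapshot,
            horizon=h,
            n_reps=n_reps,
            seed=seed,
            crn=True,
        )
        reports[name] = warning_report(res, caps)
    ref = reports[names[0]]
    rows = []
    for name in names:
        rep = reports[name]
        rows.append(
            (
                name,
                rep.bmoc,
                rep.bmoc - ref.bmoc,
                float(rep.p_capacity.max()),
                float((rep.p_capacity - ref.p_capacity).max()),
                float((rep.p_capacity - ref.p_capacity).min()),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "schedule",
            "bmoc",
            "bmoc_vs_reference",
            "max_p_capacity",
            "max_p_capacity_increase",
            "max_p_capacity_decrease",
        ],
    )
    return reports, table


# ---------------------------------------------------------------------------
# the d-parameter (EDD information) experiment
# ---------------------------------------------------------------------------


@dataclass
class EddConfig:
    """Settings of the estimated-discharge-information experiment."""

    d_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_reps: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.d_grid or any(not 0 <= d <= 1 for d in self.d_grid):
            raise DecisionError("every d must be in [0, 1]")


def edd_experiment(
    params: HospitalParameters,
    snapshot: SystemSnapshot,
    schedule: ElectiveSchedule,
    cfg: EddConfig,
    horizon: int | None = None,
) -> pd.DataFrame:
    """Occupancy dispersion as a function of the LOS-estimate accuracy d.

    For each d on the grid the symbiotic simulation is run with matched
    random streams (common random numbers across d): clinicians' estimates
    are correct with probability d per patient per replication, otherwise
    the applicable (conditional) empirical distribution is sampled.  The
    returned frame holds the standard deviation of midnight occupancy
    across replications per (d, ward, day), averaged over the day of the
    week; the initiation day is excluded.
    """
    h = horizon if horizon is not None else schedule.horizon
    rows = []
    for d in cfg.d_grid:
        res = simulate(
            params,
            schedule=schedule,
            initial=snapshot,
            horizon=h,
            n_reps=cfg.n_reps,
            seed=cfg.seed,
            d=float(d),
            crn=True,
        )
        tot = res.ward_totals()  # (reps, wards, days)
        sd = tot.std(axis=0, ddof=1)  # (wards, days)
        weekdays = res.weekdays()
        for wi, w in enumerate(res.wards):
            for wd in range(7):
                mask = (weekdays == wd) & (np.arange(res.n_days) >= 1)
                if not mask.any():
                    continue
                rows.append((float(d), w, wd, float(sd[wi, mask].mean())))
    return pd.DataFrame(rows, columns=["d", "ward", "weekday", "sd_occupancy"])
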