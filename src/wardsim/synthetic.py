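"""Synthetic-hospital generator with fully known ground truth.

The generator emulates the patient-administrative extract of a hospital
whose dynamics follow exactly the model the simulator implements: weekday-
dependent emergency arrival count distributions per ward, ward length-of-
stay distributions per (ward, admission type, arrival weekday), memoryless
ward-transition matrices per admission type, a weekly elective admission
pattern with optional non-attendance, and day-boundary transfers.  Because
the generating law and the simulated law coincide by construction, every
downstream stage (estimation, symbiotic re-initialisation, the delta-method
validation, the decision-support applications) can be tested against known
truth without any external data.

What the generator does *not* emulate: seasonality and secular trend,
case-mix or clinical covariates, bed-level locations, intra-day timing —
none of which appear in the model either.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .engine import ElectiveSchedule, ScheduleEntry, sample_pmf
from .estimation import DISCHARGE, EmpiricalPmf, HospitalParameters
from .records import ADMISSION_TYPES, ELECTIVE, EMERGENCY, WardStay
from .state import SystemSnapshot, capture_snapshot

_DEFAULT_START = dt.date(2024, 1, 1)  # a Monday


class ConfigError(ValueError):
    """Raised when a ground-truth configuration is invalid."""


@dataclass
class GroundTruthConfig:
    """A fully specified synthetic hospital.

    ``arrivals`` maps (ward, weekday) to the pmf of daily emergency
    admission counts; ``wlos`` maps (ward, admission type, weekday of
    arrival) to the WLOS pmf (support >= 1 midnight); ``transitions`` maps
    admission type to a row-stochastic matrix over wards + discharge (rows
    and columns in ``wards`` order, discharge last); ``electives`` maps a
    ward to seven planned daily admission counts, Monday first.
    """

    wards: list[str]
    arrivals: dict[tuple[str, int], EmpiricalPmf]
    wlos: dict[tuple[str, str, int], EmpiricalPmf]
    transitions: dict[str, np.ndarray]
    electives: dict[str, tuple[int, ...]] = field(default_factory=dict)
    nonattendance_prob: float = 0.0
    horizon_days: int = 560
    start_date: dt.date = _DEFAULT_START
    seed: int = 20240101

    def __post_init__(self) -> None:
        if not self.wards:
            raise ConfigError("at least one ward is required")
        if self.horizon_days < 1:
            raise ConfigError("horizon_days must be >= 1")
        if not 0 <= self.nonattendance_prob <= 1:
            raise ConfigError("nonattendance_prob must be in [0, 1]")
        n = len(self.wards)
        for t in ADMISSION_TYPES:
            if t not in self.transitions:
                raise ConfigError(f"missing transition matrix for {t!r}")
            m = np.asarray(self.transitions[t], dtype=float)
            if m.shape != (n, n + 1):
                raise ConfigError(f"transition matrix for {t!r} must be {n}x{n + 1}")
            if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError(f"transition rows for {t!r} must sum to 1")
            self.transitions[t] = m
        for (w, t, wd), pmf in self.wlos.items():
            if pmf.support[0] < 1:
                raise ConfigError(
                    f"WLOS support must start at >= 1 midnight (ward {w!r})"
                )
        for w, counts in self.electives.items():
            if w not in self.wards:
                raise ConfigError(f"elective pattern references unknown ward {w!r}")
            if len(counts) != 7 or any(c < 0 for c in counts):
                raise ConfigError("elective pattern needs 7 non-negative counts")

    # -- convenient constructors ------------------------------------------

    @classmethod
    def build(
        cls,
        wards: Sequence[str],
        emergency_rates: Mapping[str, float | Sequence[float]],
        wlos_spec: Mapping[str, Mapping[str, Mapping]],
        transitions: Mapping[str, Mapping[str, Mapping[str, float]]],
        electives: Mapping[str, Sequence[int]] | None = None,
        **kwargs,
    ) -> "GroundTruthConfig":
        """Build a config from compact per-ward specifications.

        ``emergency_rates[ward]`` is a Poisson mean (scalar, or one per
        weekday Monday-first).  ``wlos_spec[ward][type]`` is either
        ``{"geometric": p, "max": M}`` or ``{"pmf": {k: prob}}``.
        ``transitions[type][ward]`` maps destinations (other wards or
        ``"discharge"``) to probabilities; omitted mass goes to discharge.
        """
        wards = list(wards)
        arrivals: dict[tuple[str, int], EmpiricalPmf] = {}
        for w in wards:
            rate = emergency_rates.get(w, 0.0)
            rates = [float(rate)] * 7 if np.isscalar(rate) else [float(r) for r in rate]
            if len(rates) != 7:
                raise ConfigError(f"need 1 or 7 rates for ward {w!r}")
            for wd in range(7):
                arrivals[(w, wd)] = EmpiricalPmf.poisson(rates[wd])
        wlos: dict[tuple[str, str, int], EmpiricalPmf] = {}
        for w in wards:
            spec_by_type = wlos_spec[w]
            for t in ADMISSION_TYPES:
                spec = spec_by_type.get(t) or next(iter(spec_by_type.values()))
                if "geometric" in spec:
                    pmf = EmpiricalPmf.geometric(
                        spec["geometric"], spec.get("max", 60)
                    )
                elif "pmf" in spec:
                    pmf = EmpiricalPmf.from_dict(spec["pmf"])
                else:
                    raise ConfigError(f"unknown WLOS family for ward {w!r}: {spec}")
                for wd in range(7):
                    wlos[(w, t, wd)] = pmf
        tmats: dict[str, np.ndarray] = {}
        for t in ADMISSION_TYPES:
            rows = transitions.get(t, {})
            m = np.zeros((len(wards), len(wards) + 1))
            for i, w in enumerate(wards):
                row = dict(rows.get(w, {}))
                for j, w2 in enumerate(wards):
                    m[i, j] = row.pop(w2, 0.0)
                m[i, -1] = row.pop(DISCHARGE, 1.0 - m[i, :-1].sum())
                if row:
                    raise ConfigError(f"unknown transition destinations: {sorted(row)}")
            tmats[t] = m
        elect = {
            w: tuple(int(c) for c in counts)
            for w, counts in (electives or {}).items()
        }
        return cls(wards, arrivals, wlos, tmats, elect, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruthConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        kwargs = {}
        if "start_date" in doc:
            kwargs["start_date"] = dt.date.fromisoformat(str(doc["start_date"]))
        for k in ("horizon_days", "seed", "nonattendance_prob"):
            if k in doc:
                kwargs[k] = doc[k]
        return cls.build(
            wards=doc["wards"],
            emergency_rates=doc.get("emergency_rates", {}),
            wlos_spec=doc["wlos"],
            transitions=doc.get("transitions", {}),
            electives=doc.get("electives"),
            **kwargs,
        )

    @classmethod
    def default(cls) -> "GroundTruthConfig":
        """A small acute hospital: four wards with weekday structure.

        Medical and surgical admission wards with weekend dips in emergency
        arrivals, an elective orthopaedic ward, and a long-stay
        rehabilitation ward fed by transfers.
        """
        wk = lambda hi, lo: [hi, hi, hi, hi, hi, lo, lo]
        return cls.build(
            wards=["MED", "SUR", "ORT", "REH"],
            emergency_rates={
                "MED": wk(6.0, 4.5),
                "SUR": wk(3.5, 2.5),
                "ORT": wk(1.2, 0.8),
                "REH": 0.2,
            },
            wlos_spec={
                "MED": {"emergency": {"geometric": 0.28, "max": 60},
                        "elective": {"geometric": 0.40, "max": 40}},
                "SUR": {"emergency": {"geometric": 0.30, "max": 60},
                        "elective": {"geometric": 0.45, "max": 40}},
                "ORT": {"emergency": {"geometric": 0.25, "max": 60},
                        "elective": {"geometric": 0.35, "max": 40}},
                "REH": {"emergency": {"geometric": 0.10, "max": 90},
                        "elective": {"geometric": 0.10, "max": 90}},
            },
            transitions={
                "emergency": {
                    "MED": {"REH": 0.10, "SUR": 0.03},
                    "SUR": {"MED": 0.04, "REH": 0.05},
                    "ORT": {"REH": 0.08},
                    "REH": {},
                },
                "elective": {
                    "MED": {"REH": 0.05},
                    "SUR": {"MED": 0.03, "REH": 0.03},
                    "ORT": {"REH": 0.10},
                    "REH": {},
                },
            },
            electives={
                "SUR": (4, 4, 4, 4, 2, 0, 0),
                "ORT": (3, 3, 3, 3, 1, 0, 0),
                "MED": (1, 1, 1, 1, 1, 0, 0),
            },
        )

    @classmethod
    def recovery_scenario(cls, horizon_days: int = 3500) -> "GroundTruthConfig":
        """A high-volume two-ward system for parameter-recovery checks.

        Arrival volumes are chosen so every (ward, type, weekday) WLOS
        stratum holds on the order of 10,000 closed stays, which puts the
        binomial standard error of each pmf point near 0.005 — comfortably
        inside a ±0.02 pointwise recovery band across all strata at once.
        """
        return cls.build(
            wards=["A", "B"],
            emergency_rates={"A": 28.0, "B": 20.0},
            wlos_spec={
                "A": {"emergency": {"geometric": 0.40, "max": 30},
                      "elective": {"geometric": 0.50, "max": 30}},
                "B": {"emergency": {"geometric": 0.35, "max": 30},
                      "elective": {"geometric": 0.45, "max": 30}},
            },
            transitions={
                "emergency": {"A": {"B": 0.25}, "B": {"A": 0.15}},
                "elective": {"A": {"B": 0.10}, "B": {"A": 0.05}},
            },
            electives={"A": (20,) * 7, "B": (20,) * 7},
            horizon_days=horizon_days,
        )

    @classmethod
    def validation_scenario(cls, horizon_days: int = 20000) -> "GroundTruthConfig":
        """A slowly-mixing long-stay two-ward network for distributional
        self-checks of the re-initialised simulation.

        With weekly re-initialisation the simulated delta pool mixes over a
        limited number of initiation states, which adds state-sampling
        noise of order ``0.4*sqrt(h*p/2)/sqrt(#initiations)`` to the P-P
        coordinates (p the geometric WLOS rate).  A long-stay network
        (mean WLOS ~33 nights) keeps that noise well below the model
        signal, and weekday-homogeneous arrivals make the all-days observed
        pool and the Monday-initialised simulated pool estimate the same
        distribution.  This scenario is for verifying the machinery, not
        for emulating an acute hospital; see the package methods note.
        """
        return cls.build(
            wards=["LS1", "LS2"],
            emergency_rates={"LS1": 3.0, "LS2": 2.0},
            wlos_spec={
                "LS1": {"emergency": {"geometric": 0.03, "max": 200},
                        "elective": {"geometric": 0.03, "max": 200}},
                "LS2": {"emergency": {"geometric": 0.03, "max": 200},
                        "elective": {"geometric": 0.03, "max": 200}},
            },
            transitions={
                "emergency": {"LS1": {"LS2": 0.05}, "LS2": {"LS1": 0.05}},
                "elective": {"LS1": {"LS2": 0.05}, "LS2": {"LS1": 0.05}},
            },
            electives={"LS2": (1, 1, 1, 1, 1, 1, 1)},
            horizon_days=horizon_days,
        )

    # -- views -------------------------------------------------------------

    def to_parameters(self) -> HospitalParameters:
        """The exact model parameters implied by the ground truth."""
        return HospitalParameters(
            wards=list(self.wards),
            arrivals=dict(self.arrivals),
            wlos=dict(self.wlos),
            transitions={t: m.copy() for t, m in self.transitions.items()},
            nonattendance_prob=self.nonattendance_prob,
            aggregation={w: w for w in self.wards},
        )

    def weekly_schedule(
        self,
        first_day: int = 0,
        horizon: int = 7,
        start_weekday: int | None = None,
        with_truth: bool = False,
        rng: np.random.Generator | None = None,
    ) -> ElectiveSchedule:
        """Materialise the weekly elective pattern over ``[first_day, horizon]``.

        With ``with_truth`` each planned patient also carries a true length
        of stay drawn from the applicable WLOS distribution (the synthetic
        stand-in for clinicians' estimated dates of discharge).
        """
        if start_weekday is None:
            start_weekday = self.start_date.weekday()
        rng = rng or np.random.default_rng(self.seed + 1)
        entries = []
        for day in range(first_day, horizon + 1):
            wd = (start_weekday + day) % 7
            for w, pattern in sorted(self.electives.items()):
                count = pattern[wd]
                if count == 0:
                    continue
                truth = None
                if with_truth:
                    pmf = self.wlos[(w, ELECTIVE, wd)]
                    truth = tuple(
                        max(1, sample_pmf(pmf, rng.random())) for _ in range(count)
                    )
                entries.append(ScheduleEntry(day, w, count, truth))
        return ElectiveSchedule(entries, horizon)


# ---------------------------------------------------------------------------
# record generation
# ---------------------------------------------------------------------------


def generate_records(
    config: GroundTruthConfig, seed: int | None = None
) -> list[WardStay]:
    """Generate a ward-stay record set from the ground truth.

    Arrivals are generated for every day in ``[start_date, start_date +
    horizon_days)``; transfer chains run to completion, so departures may
    fall beyond the horizon (as in a real extract, where the observation
    window is on admissions).  Reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    widx = {w: i for i, w in enumerate(config.wards)}
    trans_cum = {t: np.cumsum(m, axis=1) for t, m in config.transitions.items()}
    start_wd = config.start_date.weekday()
    stays: list[WardStay] = []
    pid = 0

    def admit(day: int, ward: str, admission_type: str) -> None:
        nonlocal pid
        pid += 1
        patient = f"P{pid:07d}"
        admission_date = config.start_date + dt.timedelta(days=day)
        cur_ward, cur_day = ward, day
        while True:
            wd = (start_wd + cur_day) % 7
            nights = sample_pmf(config.wlos[(cur_ward, admission_type, wd)], rng.random())
            end_day = cur_day + nights
            stays.append(
                WardStay(
                    patient_id=patient,
                    ward=cur_ward,
                    admission_type=admission_type,
                    arrival_date=config.start_date + dt.timedelta(days=cur_day),
                    departure_date=config.start_date + dt.timedelta(days=end_day),
                    hospital_admission_date=admission_date,
                )
            )
            row = trans_cum[admission_type][widx[cur_ward]]
            dest = int(np.searchsorted(row, rng.random(), side="right"))
            if dest >= len(config.wards):
                return  # discharged
            cur_ward, cur_day = config.wards[dest], end_day

    q = config.nonattendance_prob
    for day in range(config.horizon_days):
        wd = (start_wd + day) % 7
        for w in config.wards:
            n_emerg = sample_pmf(config.arrivals[(w, wd)], rng.random())
            for _ in range(n_emerg):
                admit(day, w, EMERGENCY)
        for w, pattern in sorted(config.electives.items()):
            for _ in range(pattern[wd]):
                if q > 0 and rng.random() < q:
                    continue
                admit(day, w, ELECTIVE)
    return stays


def generate_snapshot(
    config: GroundTruthConfig,
    warmup_days: int,
    seed: int | None = None,
    return_records: bool = False,
):
    """Run the generator for ``warmup_days`` and capture the resident state.

    The capture midnight is ``start_date + warmup_days``; admissions are
    generated up to and including the capture day, so the snapshot is the
    census of a hospital that has been running long enough to forget its
    empty start (choose ``warmup_days`` comfortably above the WLOS
    support).  Every resident carries their true remaining length of stay
    (``known_remaining``), which downstream code may use as a test oracle
    or as the perfect-information source of the estimated-discharge
    experiment.
    """
    run = GroundTruthConfig(
        wards=config.wards,
        arrivals=config.arrivals,
        wlos=config.wlos,
        transitions=config.transitions,
        electives=config.electives,
        nonattendance_prob=config.nonattendance_prob,
        horizon_days=warmup_days + 1,
        start_date=config.start_date,
        seed=config.seed if seed is None else seed,
    )
    stays = generate_records(run)
    capture = config.start_date + dt.timedelta(days=warmup_days)
    snapshot = capture_snapshot(stays, capture)
    return (snapshot, stays) if return_records else snapshot
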