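"""System-state snapshots and conditional remaining length-of-stay.

A symbiotic simulation is re-initialised from the state of the physical
system: for every patient resident at the capture midnight we record their
ward, admission type, weekday of arrival at the ward, and the elapsed time
``s`` (in midnights) already spent on the ward.  A resident's *remaining*
stay ``R = T - s`` is then sampled from the marginal WLOS distribution
``F_T`` conditioned on survival to ``s``:

    F_R(r, s) = (F_T(s + r) - F_T(s - 1)) / (1 - F_T(s - 1)),

with the convention ``F_T(-1) = 0`` so that ``s = 0`` reduces to the
unconditional distribution.  Realisations of ``R`` are drawn by inverse
transform sampling; ``r = 0`` means the patient departs at the next
midnight boundary.  For a geometric ``F_T`` the conditional distribution is
(up to truncation) independent of ``s`` — the memoryless property — but the
empirical WLOS distributions used here are not memoryless, which is why the
conditioning matters.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .estimation import EmpiricalPmf
from .records import (
    ADMISSION_TYPES,
    RecordError,
    WEEKDAY_NAMES,
    WardStay,
    exclude_same_day,
)

logger = logging.getLogger("wardsim")


class StateError(ValueError):
    """Raised for invalid snapshots or conditional distributions."""


@dataclass(frozen=True)
class Resident:
    """One patient occupying a bed at the capture midnight."""

    patient_id: str
    ward: str
    admission_type: str
    arrival_weekday: int  # weekday of arrival at the current ward, MON = 0
    elapsed: int  # midnights between ward arrival and capture date
    known_remaining: int | None = None  # true remaining midnights incl. capture

    def __post_init__(self) -> None:
        if self.elapsed < 0:
            raise StateError("elapsed midnights must be >= 0")
        if not 0 <= self.arrival_weekday < 7:
            raise StateError("arrival_weekday must be in 0..6")
        if self.admission_type not in ADMISSION_TYPES:
            raise StateError(f"bad admission type {self.admission_type!r}")
        if self.known_remaining is not None and self.known_remaining < 1:
            raise StateError("known_remaining must be >= 1 when present")


@dataclass
class SystemSnapshot:
    """The physical-system state at one capture midnight."""

    capture_date: dt.date
    residents: list[Resident] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residents)

    def ward_counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for r in self.residents:
            out[(r.ward, r.admission_type)] = out.get((r.ward, r.admission_type), 0) + 1
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["capture_date", self.capture_date.isoformat()])
            writer.writerow(
                [
                    "patient_id",
                    "ward",
                    "admission_type",
                    "arrival_weekday",
                    "elapsed_midnights",
                    "known_remaining",
                ]
            )
            for r in self.residents:
                writer.writerow(
                    [
                        r.patient_id,
                        r.ward,
                        r.admission_type,
                        WEEKDAY_NAMES[r.arrival_weekday],
                        r.elapsed,
                        "" if r.known_remaining is None else r.known_remaining,
                    ]
                )

    @classmethod
    def from_csv(cls, path) -> "SystemSnapshot":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            head = next(reader)
            if not head or head[0] != "capture_date":
                raise StateError(f"{path}: missing capture_date header line")
            capture = dt.date.fromisoformat(head[1])
            header = next(reader)
            residents = []
            for row in reader:
                rec = dict(zip(header, row))
                residents.append(
                    Resident(
                        patient_id=rec["patient_id"],
                        ward=rec["ward"],
                        admission_type=rec["admission_type"],
                        arrival_weekday=WEEKDAY_NAMES.index(rec["arrival_weekday"]),
                        elapsed=int(rec["elapsed_midnights"]),
                        known_remaining=int(rec["known_remaining"])
                        if rec.get("known_remaining")
                        else None,
                    )
                )
        return cls(capture, residents)


def capture_snapshot(stays: Sequence[WardStay], date: dt.date) -> SystemSnapshot:
    """Snapshot of all patients resident at the midnight of ``date``.

    A patient is resident on ward w iff they have a stay there with
    ``arrival <= date < departure`` (open stays count).  Same-day spells are
    excluded, mirroring the census metric.  When the stay is closed the true
    remaining length of stay (midnights from the capture date to departure,
    inclusive of the capture midnight) is recorded so it can serve, e.g., as
    a retrospective estimated-date-of-discharge information source.
    """
    residents = []
    for s in exclude_same_day(stays):
        if s.arrival_date <= date and (s.departure_date is None or date < s.departure_date):
            residents.append(
                Resident(
                    patient_id=s.patient_id,
                    ward=s.ward,
                    admission_type=s.admission_type,
                    arrival_weekday=s.arrival_weekday,
                    elapsed=(date - s.arrival_date).days,
                    known_remaining=None
                    if s.departure_date is None
                    else (s.departure_date - date).days,
                )
            )
    return SystemSnapshot(date, residents)


# ---------------------------------------------------------------------------
# conditional distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionalCdf:
    """Remaining-LOS distribution R = T - s given survival to s.

    ``effective_s`` is ``s`` after clamping to the largest elapsed time with
    positive survival probability under ``base`` (long-stayers outside the
    empirical support are kept in-system rather than erroring).
    """

    base: EmpiricalPmf
    s: int
    effective_s: int
    pmf: EmpiricalPmf  # over r >= 0


def conditional_cdf(f_t: EmpiricalPmf, s: int) -> ConditionalCdf:
    """Condition the total-LOS pmf on ``T >= s`` and shift to R = T - s.

    Implements F_R(r, s) = (F_T(s + r) - F_T(s - 1)) / (1 - F_T(s - 1)),
    with F_T(-1) = 0; pointwise, P(R = r) = P(T = s + r) / P(T >= s) on the
    support ``r in {max(0, min_support - s), ..., max_support - s}``.
    """
    if s < 0:
        raise StateError("elapsed time s must be >= 0")
    eff = int(s)
    if f_t.sf_at(eff) <= 0:
        # clamp to the largest s' with P(T >= s') > 0, i.e. the top of support
        eff = f_t.max_support()
        logger.warning(
            "elapsed time %d exceeds the WLOS support; clamped to %d", s, eff
        )
    denom = f_t.sf_at(eff)
    support = []
    probs = []
    for x, p in zip(f_t.support, f_t.probabilities):
        if x >= eff and p > 0:
            support.append(x - eff)
            probs.append(p / denom)
    pmf = EmpiricalPmf(tuple(support), tuple(np.asarray(probs) / np.sum(probs)),
                       f_t.sample_size)
    return ConditionalCdf(base=f_t, s=int(s), effective_s=eff, pmf=pmf)


def sample_remaining(cond: ConditionalCdf, u: float) -> int:
    """Inverse-transform draw of the remaining LOS r >= 0.

    Returns the smallest support value whose conditional CDF exceeds ``u``;
    ``r = 0`` means the patient departs at the next midnight boundary.
    """
    from .engine import sample_pmf

    return sample_pmf(cond.pmf, u)
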