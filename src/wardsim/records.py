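"""Ward-stay records and the midnight bed census.

The patient-administrative extract is modelled as a flat list of ward-stay
segments: one contiguous occupancy of one ward by one patient.  A patient's
*spell* (full hospital stay) is the chain of ward stays sharing a patient id
and hospital admission date.  The operational metric throughout the package
is the midnight bed census: the number of patients occupying beds on a ward
at midnight, split by admission type, after excluding spells that are
admitted and discharged on the same calendar day.

Date convention: days are calendar dates at day granularity and a stay
``[arrival, departure)`` is half-open, so a patient is present at the
midnight of day ``t`` iff ``arrival <= t < departure``.  The ward length of
stay in midnights is then exactly ``departure - arrival``.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("wardsim")

EMERGENCY = "emergency"
ELECTIVE = "elective"
ADMISSION_TYPES = (EMERGENCY, ELECTIVE)

#: canonical weekday names, Monday first (aligned with ``date.weekday()``)
WEEKDAY_NAMES = ("MON", "TUE", "WED", "THU", "FRI", "SAT", "SUN")

#: default column names of the ward-stay CSV dialect
DEFAULT_COLUMNS = (
    "patient_id",
    "ward",
    "admission_type",
    "arrival_date",
    "departure_date",
    "hospital_admission_date",
)


class RecordError(ValueError):
    """A ward-stay record or record file violates the data contract."""


@dataclass(frozen=True)
class WardStay:
    """One contiguous occupancy of one ward by one patient.

    ``departure_date is None`` marks a stay that is still open (the patient
    was resident when the extract was taken).
    """

    patient_id: str
    ward: str
    admission_type: str
    arrival_date: dt.date
    departure_date: dt.date | None
    hospital_admission_date: dt.date

    def __post_init__(self) -> None:
        if self.admission_type not in ADMISSION_TYPES:
            raise RecordError(
                f"admission_type must be one of {ADMISSION_TYPES}, "
                f"got {self.admission_type!r}"
            )
        if self.departure_date is not None and self.departure_date < self.arrival_date:
            raise RecordError(
                f"departure {self.departure_date} before arrival {self.arrival_date}"
            )
        if self.hospital_admission_date > self.arrival_date:
            raise RecordError(
                "hospital_admission_date after ward arrival "
                f"({self.hospital_admission_date} > {self.arrival_date})"
            )

    @property
    def is_open(self) -> bool:
        return self.departure_date is None

    @property
    def arrival_weekday(self) -> int:
        """Weekday of arrival at this ward, Monday = 0."""
        return self.arrival_date.weekday()


def wlos_midnights(stay: WardStay) -> int:
    """Ward length of stay: midnights spent on the ward.

    Equals ``departure - arrival`` in days under the half-open convention;
    a same-day ward stay has zero midnights.
    """
    if stay.departure_date is None:
        raise RecordError("wlos_midnights is undefined for an open stay")
    return (stay.departure_date - stay.arrival_date).days


def spell_key(stay: WardStay) -> tuple[str, dt.date]:
    return (stay.patient_id, stay.hospital_admission_date)


def same_day_spells(stays: Iterable[WardStay]) -> set[tuple[str, dt.date]]:
    """Spells whose hospital admission and final discharge share one date.

    These never contribute a midnight and are excluded from the census
    metric.  A spell with any open stay is not same-day.
    """
    last_exit: dict[tuple[str, dt.date], dt.date | None] = {}
    for s in stays:
        k = spell_key(s)
        if s.departure_date is None:
            last_exit[k] = None
        elif k not in last_exit:
            last_exit[k] = s.departure_date
        elif last_exit[k] is not None:
            last_exit[k] = max(last_exit[k], s.departure_date)  # type: ignore[type-var]
    return {
        k
        for k, out in last_exit.items()
        if out is not None and out == k[1]
    }


def exclude_same_day(stays: Sequence[WardStay]) -> list[WardStay]:
    """Drop every stay of a same-day spell (spell-level exclusion)."""
    bad = same_day_spells(stays)
    return [s for s in stays if spell_key(s) not in bad]


# ---------------------------------------------------------------------------
# census trajectory
# ---------------------------------------------------------------------------


@dataclass
class CensusTrajectory:
    """Midnight occupancy per (ward, day, admission type).

    ``counts`` has shape ``(n_wards, n_days, 2)`` with the last axis indexed
    by :data:`ADMISSION_TYPES` (emergency, elective).
    """

    wards: list[str]
    start_date: dt.date
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (n_wards, n_days, 2)")
        if self.counts.shape[0] != len(self.wards):
            raise ValueError("ward axis does not match ward list")
        if (self.counts < 0).any():
            raise ValueError("census counts must be non-negative")

    @property
    def n_days(self) -> int:
        return self.counts.shape[1]

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(self.n_days)]

    def weekdays(self) -> np.ndarray:
        w0 = self.start_date.weekday()
        return (w0 + np.arange(self.n_days)) % 7

    def ward_index(self, ward: str) -> int:
        try:
            return self.wards.index(ward)
        except ValueError:
            raise KeyError(f"unknown ward {ward!r}") from None

    def series(self, ward: str, admission_type: str | None = None) -> np.ndarray:
        """Daily occupancy of one ward, totalled over types by default."""
        row = self.counts[self.ward_index(ward)]
        if admission_type is None:
            return row.sum(axis=1)
        return row[:, ADMISSION_TYPES.index(admission_type)]

    def total(self, admission_type: str | None = None) -> np.ndarray:
        """Hospital-wide daily occupancy."""
        if admission_type is None:
            return self.counts.sum(axis=(0, 2))
        return self.counts[:, :, ADMISSION_TYPES.index(admission_type)].sum(axis=0)

    def mean_occupancy(self) -> dict[str, float]:
        return {
            w: float(self.counts[i].sum(axis=1).mean())
            for i, w in enumerate(self.wards)
        }

    def aggregate(self, mapping: Mapping[str, str]) -> "CensusTrajectory":
        """Relabel wards through ``mapping`` (e.g. collapse into 'Other')."""
        new_wards = sorted({mapping.get(w, w) for w in self.wards})
        out = np.zeros((len(new_wards), self.n_days, 2), dtype=np.int64)
        for i, w in enumerate(self.wards):
            out[new_wards.index(mapping.get(w, w))] += self.counts[i]
        return CensusTrajectory(new_wards, self.start_date, out)

    def slice_days(self, first: int, last: int | None = None) -> "CensusTrajectory":
        """Restrict to day indices ``[first, last)``."""
        return CensusTrajectory(
            list(self.wards),
            self.start_date + dt.timedelta(days=first),
            self.counts[:, first:last].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: ward, date, admission_type, count."""
        dates = self.dates()
        rows = []
        for i, w in enumerate(self.wards):
            for j, d in enumerate(dates):
                for k, t in enumerate(ADMISSION_TYPES):
                    rows.append((w, d.isoformat(), t, int(self.counts[i, j, k])))
        return pd.DataFrame(rows, columns=["ward", "date", "admission_type", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def derive_census(
    stays: Sequence[WardStay],
    start: dt.date | None = None,
    end: dt.date | None = None,
    wards: Sequence[str] | None = None,
) -> CensusTrajectory:
    """Midnight bed census over ``[start, end)`` from ward-stay records.

    A patient counts towards ward ``w`` at midnight ``t`` iff they have a
    stay on ``w`` with ``arrival <= t < departure``; open stays count
    through the end of the range.  Spells admitted and discharged on the
    same day are excluded entirely.
    """
    kept = exclude_same_day(stays)
    if start is None or end is None:
        if not kept:
            raise RecordError("cannot infer a census range from no records")
        dates = [s.arrival_date for s in kept]
        dep = [s.departure_date for s in kept if s.departure_date is not None]
        inferred_start = min(dates)
        inferred_end = max(dep + dates) + dt.timedelta(days=1)
        start = start or inferred_start
        end = end or inferred_end
    n_days = (end - start).days
    if n_days <= 0:
        raise RecordError("census range is empty")
    ward_list = sorted(wards) if wards is not None else sorted({s.ward for s in kept})
    idx = {w: i for i, w in enumerate(ward_list)}
    counts = np.zeros((len(ward_list), n_days, 2), dtype=np.int64)
    for s in kept:
        if s.ward not in idx:
            continue
        a = (s.arrival_date - start).days
        b = n_days if s.departure_date is None else (s.departure_date - start).days
        a, b = max(a, 0), min(b, n_days)
        if a < b:
            counts[idx[s.ward], a:b, ADMISSION_TYPES.index(s.admission_type)] += 1
    return CensusTrajectory(ward_list, start, counts)


# ---------------------------------------------------------------------------
# CSV reader / writer
# ---------------------------------------------------------------------------


def _parse_date(text: str, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise RecordError(f"row {row}: unparseable date {text!r} in {column}") from None


def read_ward_stays(
    path,
    dialect: Mapping[str, str] | None = None,
    rejects: list | None = None,
) -> list[WardStay]:
    """Read ward-stay records from CSV.

    ``dialect`` maps canonical column names to the file's column names.
    Rows with unparseable dates or invariant violations are rejected and
    reported (appended to ``rejects`` as ``(row_number, reason)`` when a
    list is supplied, and counted in a log warning); a missing column is a
    configuration error.
    """
    colmap = dict(dialect or {})
    stays: list[WardStay] = []
    n_rejected = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in DEFAULT_COLUMNS:
            if colmap.get(canonical, canonical) not in header:
                raise RecordError(
                    f"required column {colmap.get(canonical, canonical)!r} "
                    f"(for {canonical}) missing from {path}"
                )
        for row_no, row in enumerate(reader, start=2):
            try:
                get = lambda c: (row.get(colmap.get(c, c)) or "").strip()
                dep_text = get("departure_date")
                stay = WardStay(
                    patient_id=get("patient_id"),
                    ward=get("ward"),
                    admission_type=get("admission_type"),
                    arrival_date=_parse_date(get("arrival_date"), row_no, "arrival_date"),
                    departure_date=None
                    if not dep_text
                    else _parse_date(dep_text, row_no, "departure_date"),
                    hospital_admission_date=_parse_date(
                        get("hospital_admission_date"), row_no, "hospital_admission_date"
                    ),
                )
            except RecordError as exc:
                n_rejected += 1
                if rejects is not None:
                    rejects.append((row_no, str(exc)))
                continue
            stays.append(stay)
    if n_rejected:
        logger.warning("%s: rejected %d invalid ward-stay rows", path, n_rejected)
    return stays


def write_ward_stays(path, stays: Iterable[WardStay]) -> None:
    """Write records in the canonical CSV dialect (round-trips exactly)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DEFAULT_COLUMNS)
        for s in stays:
            writer.writerow(
                [
                    s.patient_id,
                    s.ward,
                    s.admission_type,
                    s.arrival_date.isoformat(),
                    "" if s.departure_date is None else s.departure_date.isoformat(),
                    s.hospital_admission_date.isoformat(),
                ]
            )
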