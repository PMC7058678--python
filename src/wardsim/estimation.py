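"""Estimation of simulator parameters from ward-stay records.

Everything the simulator consumes is estimated empirically, in keeping with
the data-driven character of a symbiotic simulation:

* daily emergency admission counts per (ward, weekday) as empirical pmfs,
* ward length-of-stay (WLOS) pmfs per (ward, admission type, weekday of
  arrival at the ward),
* ward-to-ward transition probabilities per admission type, with discharge
  as an absorbing destination, estimated as the proportion of departures
  from each ward moving to each subsequent ward or out of hospital.

Wards are selected so that the individually modelled ones cover a target
share (default 90%) of mean midnight occupancy; the remainder are pooled
into a pseudo-ward ``"Other"`` so the population of interest is captured
entirely.  Transitions are memoryless in the ward chain: the destination
depends only on the current ward and admission type.

Spells admitted and discharged on the same calendar day are excluded from
all estimators, mirroring their exclusion from the census metric.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import (
    ADMISSION_TYPES,
    CensusTrajectory,
    RecordError,
    WardStay,
    exclude_same_day,
    spell_key,
    wlos_midnights,
)

OTHER_WARD = "Other"
DISCHARGE = "discharge"

_PROB_TOL = 1e-9


class EstimationError(ValueError):
    """Raised when records cannot support a requested estimate."""


@dataclass(frozen=True)
class EmpiricalPmf:
    """A probability mass function on a sorted integer support."""

    support: tuple[int, ...]
    probabilities: tuple[float, ...]
    sample_size: int = 0

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probabilities) or not self.support:
            raise ValueError("support and probabilities must match and be non-empty")
        if any(b <= a for a, b in zip(self.support, self.support[1:])):
            raise ValueError("support must be strictly increasing")
        p = np.asarray(self.probabilities, dtype=float)
        if (p < -_PROB_TOL).any():
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_samples(cls, values: Iterable[int]) -> "EmpiricalPmf":
        counter = Counter(int(v) for v in values)
        if not counter:
            raise ValueError("cannot build a pmf from an empty sample")
        n = sum(counter.values())
        support = tuple(sorted(counter))
        return cls(support, tuple(counter[x] / n for x in support), n)

    @classmethod
    def from_dict(cls, table: Mapping[int, float], sample_size: int = 0) -> "EmpiricalPmf":
        support = tuple(sorted(int(k) for k in table))
        probs = np.array([float(table[k]) for k in support])
        probs = probs / probs.sum()
        return cls(support, tuple(probs), sample_size)

    @classmethod
    def point_mass(cls, value: int) -> "EmpiricalPmf":
        return cls((int(value),), (1.0,), 0)

    @classmethod
    def geometric(cls, p: float, max_support: int) -> "EmpiricalPmf":
        """Geometric number of midnights on {1, ..., max_support} (renormalised)."""
        if not 0 < p <= 1:
            raise ValueError("geometric rate must be in (0, 1]")
        k = np.arange(1, max_support + 1)
        w = p * (1 - p) ** (k - 1)
        w = w / w.sum()
        return cls(tuple(int(x) for x in k), tuple(w), 0)

    @classmethod
    def poisson(cls, lam: float, tail: float = 1e-9) -> "EmpiricalPmf":
        """Poisson counts truncated where the upper tail drops below ``tail``."""
        from scipy.stats import poisson as _pois

        if lam < 0:
            raise ValueError("Poisson rate must be >= 0")
        if lam == 0:
            return cls.point_mass(0)
        hi = int(_pois.isf(tail, lam)) + 1
        k = np.arange(0, hi + 1)
        w = _pois.pmf(k, lam)
        w = w / w.sum()
        return cls(tuple(int(x) for x in k), tuple(w), 0)

    # -- views -------------------------------------------------------------

    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.probabilities)
        c[-1] = 1.0
        return c

    def cdf_at(self, x: int) -> float:
        """F(x) = P(X <= x), with F = 0 left of the support."""
        i = np.searchsorted(self.support, x, side="right")
        return 0.0 if i == 0 else float(self.cdf()[i - 1])

    def sf_at(self, x: int) -> float:
        """P(X >= x)."""
        return 1.0 - self.cdf_at(x - 1)

    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    def var(self) -> float:
        m = self.mean()
        return float(np.dot((np.asarray(self.support) - m) ** 2, self.probabilities))

    def max_support(self) -> int:
        return self.support[-1]

    def to_dict(self) -> dict:
        return {
            "support": list(self.support),
            "probabilities": list(self.probabilities),
            "sample_size": self.sample_size,
        }


# ---------------------------------------------------------------------------
# ward selection
# ---------------------------------------------------------------------------


def select_wards(
    census: CensusTrajectory, coverage: float = 0.9
) -> tuple[list[str], dict[str, str]]:
    """Choose the individually modelled wards.

    Wards are ranked by mean midnight occupancy (descending, ties broken by
    label); the shortest prefix whose cumulative share reaches ``coverage``
    is modelled individually and every remaining ward maps to ``"Other"``.
    """
    if not 0 < coverage <= 1:
        raise EstimationError("coverage must be in (0, 1]")
    means = census.mean_occupancy()
    if not means:
        raise EstimationError("empty census: no wards to select")
    total = sum(means.values())
    if total == 0:
        raise EstimationError("census is identically zero")
    ranked = sorted(means, key=lambda w: (-means[w], w))
    modelled: list[str] = []
    cum = 0.0
    for w in ranked:
        modelled.append(w)
        cum += means[w] / total
        if cum >= coverage - _PROB_TOL:
            break
    mapping = {w: (w if w in modelled else OTHER_WARD) for w in census.wards}
    return modelled, mapping


def apply_aggregation(
    stays: Sequence[WardStay], mapping: Mapping[str, str]
) -> list[WardStay]:
    """Relabel ward names through the aggregation map."""
    out = []
    for s in stays:
        w = mapping.get(s.ward, s.ward)
        out.append(s if w == s.ward else WardStay(
            s.patient_id, w, s.admission_type, s.arrival_date,
            s.departure_date, s.hospital_admission_date,
        ))
    return out


def _modelled_wards(mapping: Mapping[str, str]) -> list[str]:
    wards = sorted({v for v in mapping.values() if v != OTHER_WARD})
    if any(v == OTHER_WARD for v in mapping.values()):
        wards.append(OTHER_WARD)
    return wards


def _record_span(stays: Sequence[WardStay]) -> tuple[dt.date, dt.date]:
    if not stays:
        raise EstimationError("no records")
    lo = min(s.arrival_date for s in stays)
    hi = max(
        [s.departure_date for s in stays if s.departure_date is not None]
        + [s.arrival_date for s in stays]
    )
    return lo, hi


# ---------------------------------------------------------------------------
# component estimators
# ---------------------------------------------------------------------------


def estimate_arrivals(
    stays: Sequence[WardStay],
    mapping: Mapping[str, str],
    span: tuple[dt.date, dt.date] | None = None,
) -> dict[tuple[str, int], EmpiricalPmf]:
    """Empirical pmf of daily emergency admission counts per (ward, weekday).

    An arrival is an emergency *hospital* admission at the ward (ward
    arrival coinciding with hospital admission); onward transfers are
    produced by the transition process, not the arrival process.  Days with
    no arrivals contribute zeros, over the full record span.
    """
    kept = apply_aggregation(exclude_same_day(stays), mapping)
    lo, hi = span if span is not None else _record_span(kept)
    n_days_by_weekday = Counter(
        (lo + dt.timedelta(days=i)).weekday() for i in range((hi - lo).days + 1)
    )
    wards = _modelled_wards(mapping)
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for s in kept:
        if s.admission_type != "emergency" or s.arrival_date != s.hospital_admission_date:
            continue
        if not lo <= s.arrival_date <= hi:
            continue
        counts[(s.ward, s.arrival_weekday)][s.arrival_date] += 1
    out: dict[tuple[str, int], EmpiricalPmf] = {}
    for w in wards:
        for wd in range(7):
            per_day = counts.get((w, wd), Counter())
            n_days = n_days_by_weekday.get(wd, 0)
            if n_days == 0:
                out[(w, wd)] = EmpiricalPmf.point_mass(0)
                continue
            values = list(per_day.values()) + [0] * (n_days - len(per_day))
            out[(w, wd)] = EmpiricalPmf.from_samples(values)
    return out


def estimate_wlos(
    stays: Sequence[WardStay], mapping: Mapping[str, str]
) -> dict[tuple[str, str, int], EmpiricalPmf]:
    """WLOS pmfs per (ward, admission type, weekday of ward arrival).

    Closed stays only.  Sparse strata fall back through the pooling ladder
    (ward, type, weekday) -> (ward, type) -> (ward) -> global; the first
    non-empty level supplies the pmf.  A ward with no closed stays at all is
    an error.
    """
    kept = [
        s for s in apply_aggregation(exclude_same_day(stays), mapping) if not s.is_open
    ]
    wards = _modelled_wards(mapping)
    by_stratum: dict[tuple[str, str, int], list[int]] = defaultdict(list)
    by_ward_type: dict[tuple[str, str], list[int]] = defaultdict(list)
    by_ward: dict[str, list[int]] = defaultdict(list)
    everything: list[int] = []
    for s in kept:
        n = wlos_midnights(s)
        by_stratum[(s.ward, s.admission_type, s.arrival_weekday)].append(n)
        by_ward_type[(s.ward, s.admission_type)].append(n)
        by_ward[s.ward].append(n)
        everything.append(n)
    if not everything:
        raise EstimationError("no closed stays from which to estimate WLOS")
    out: dict[tuple[str, str, int], EmpiricalPmf] = {}
    for w in wards:
        if not by_ward.get(w):
            raise EstimationError(f"ward {w!r} has no closed stays in any stratum")
        for t in ADMISSION_TYPES:
            for wd in range(7):
                samples = (
                    by_stratum.get((w, t, wd))
                    or by_ward_type.get((w, t))
                    or by_ward.get(w)
                    or everything
                )
                out[(w, t, wd)] = EmpiricalPmf.from_samples(samples)
    return out


def estimate_transitions(
    stays: Sequence[WardStay], mapping: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Row-stochastic transition matrices over wards + discharge, per type.

    pi[i, j] is the proportion of departures from ward i (of that admission
    type) whose next ward stay in the same spell starts at ward j on the
    departure date; the final column is discharge.  Open stays contribute no
    departure themselves but do resolve the destination of the transfer
    that started them.  A ward with no observed departures defaults to
    certain discharge.
    """
    kept = apply_aggregation(exclude_same_day(stays), mapping)
    wards = _modelled_wards(mapping)
    widx = {w: i for i, w in enumerate(wards)}
    by_spell: dict[tuple[str, dt.date], list[WardStay]] = defaultdict(list)
    for s in kept:
        by_spell[spell_key(s)].append(s)
    tallies = {t: np.zeros((len(wards), len(wards) + 1)) for t in ADMISSION_TYPES}
    for segs in by_spell.values():
        segs.sort(key=lambda s: (s.arrival_date, s.departure_date or dt.date.max))
        for cur, nxt in zip(segs, segs[1:] + [None]):
            if cur.is_open:
                continue
            dest = len(wards)  # discharge
            if nxt is not None and nxt.arrival_date == cur.departure_date:
                dest = widx[nxt.ward]
            tallies[cur.admission_type][widx[cur.ward], dest] += 1
    out = {}
    for t, m in tallies.items():
        rows = m.sum(axis=1, keepdims=True)
        pi = np.divide(m, rows, out=np.zeros_like(m), where=rows > 0)
        pi[rows[:, 0] == 0, -1] = 1.0  # no departures observed: certain discharge
        out[t] = pi
    return out


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------


@dataclass
class HospitalParameters:
    """Every estimated input the simulator needs.

    ``transitions[type]`` is a row-stochastic matrix with one row per ward
    (in ``wards`` order) and destinations ``wards + [discharge]``.
    """

    wards: list[str]
    arrivals: dict[tuple[str, int], EmpiricalPmf]
    wlos: dict[tuple[str, str, int], EmpiricalPmf]
    transitions: dict[str, np.ndarray]
    nonattendance_prob: float = 0.0
    aggregation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, m in self.transitions.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (len(self.wards), len(self.wards) + 1):
                raise EstimationError(f"transition matrix for {t!r} has wrong shape")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9) or (m < 0).any():
                raise EstimationError(f"transition rows for {t!r} are not stochastic")
            self.transitions[t] = m
        if not 0 <= self.nonattendance_prob <= 1:
            raise EstimationError("nonattendance_prob must be in [0, 1]")
        for (w, wd), pmf in self.arrivals.items():
            if w not in self.wards:
                raise EstimationError(f"arrival pmf references unknown ward {w!r}")
        for (w, t, wd) in self.wlos:
            if w not in self.wards:
                raise EstimationError(f"WLOS pmf references unknown ward {w!r}")

    def ward_index(self, ward: str) -> int:
        return self.wards.index(ward)

    def arrival_pmf(self, ward: str, weekday: int) -> EmpiricalPmf:
        return self.arrivals.get((ward, weekday)) or EmpiricalPmf.point_mass(0)

    def wlos_pmf(self, ward: str, admission_type: str, weekday: int) -> EmpiricalPmf:
        try:
            return self.wlos[(ward, admission_type, weekday)]
        except KeyError:
            raise EstimationError(
                f"no WLOS pmf for ({ward!r}, {admission_type!r}, weekday {weekday})"
            ) from None

    # -- serialisation (exact round-trip through JSON) ---------------------

    def to_json(self, path) -> None:
        doc = {
            "wards": self.wards,
            "nonattendance_prob": self.nonattendance_prob,
            "aggregation": self.aggregation,
            "arrivals": [
                {"ward": w, "weekday": wd, **pmf.to_dict()}
                for (w, wd), pmf in sorted(self.arrivals.items())
            ],
            "wlos": [
                {"ward": w, "admission_type": t, "weekday": wd, **pmf.to_dict()}
                for (w, t, wd), pmf in sorted(self.wlos.items())
            ],
            "transitions": {t: m.tolist() for t, m in self.transitions.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HospitalParameters":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            wards=list(doc["wards"]),
            arrivals={
                (e["ward"], int(e["weekday"])): EmpiricalPmf(
                    tuple(e["support"]), tuple(e["probabilities"]), e["sample_size"]
                )
                for e in doc["arrivals"]
            },
            wlos={
                (e["ward"], e["admission_type"], int(e["weekday"])): EmpiricalPmf(
                    tuple(e["support"]), tuple(e["probabilities"]), e["sample_size"]
                )
                for e in doc["wlos"]
            },
            transitions={t: np.array(m) for t, m in doc["transitions"].items()},
            nonattendance_prob=float(doc.get("nonattendance_prob", 0.0)),
            aggregation=dict(doc.get("aggregation", {})),
        )


def estimate_parameters(
    stays: Sequence[WardStay],
    coverage: float = 0.9,
    nonattendance_prob: float = 0.0,
    census: CensusTrajectory | None = None,
) -> HospitalParameters:
    """Full estimation pipeline: ward selection + all three components."""
    from .records import derive_census

    if census is None:
        census = derive_census(stays)
    modelled, mapping = select_wards(census, coverage)
    return HospitalParameters(
        wards=_modelled_wards(mapping),
        arrivals=estimate_arrivals(stays, mapping),
        wlos=estimate_wlos(stays, mapping),
        transitions=estimate_transitions(stays, mapping),
        nonattendance_prob=nonattendance_prob,
        aggregation=mapping,
    )
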