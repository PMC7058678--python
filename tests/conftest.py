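import datetime as dt

import pytest

from wardsim import GroundTruthConfig, WardStay

MON = dt.date(2024, 1, 1)  # a Monday


def day(i: int) -> dt.date:
    return MON + dt.timedelta(days=i)


def stay(pid, ward, a, b, admission_type="emergency", adm=None):
    """Shorthand: dates given as day offsets from the Monday origin."""
    return WardStay(
        patient_id=pid,
        ward=ward,
        admission_type=admission_type,
        arrival_date=day(a),
        departure_date=None if b is None else day(b),
        hospital_admission_date=day(adm if adm is not None else a),
    )


@pytest.fixture
def tiny_stays():
    return [
        stay("p1", "A", 0, 3),
        stay("p2", "A", 1, 4),
        stay("p3", "B", 2, 2),  # same-day spell: excluded from the census
        stay("p4", "B", 0, 2),
    ]


@pytest.fixture(scope="session")
def small_hospital():
    """The default acute hospital at a short horizon, with its records."""
    import wardsim as ws

    cfg = GroundTruthConfig.default()
    cfg.horizon_days = 150
    stays = ws.generate_records(cfg, seed=40)
    return cfg, stays
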