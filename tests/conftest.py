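import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prickle.records import (
    AUTUMN,
    NOT_DETECTED,
    SPRING,
    CaptureEvent,
    CaptureHistory,
    Dataset,
    infer_occasions,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_occasions(n, start_year=2014, skip=()):
    """n chronological (season, year) slots from spring of start_year,
    optionally skipping some (season, year) pairs."""
    slots = []
    year, season = start_year, SPRING
    while len(slots) < n:
        if (season, year) not in skip:
            slots.append((season, year))
        season, year = (AUTUMN, year) if season == SPRING else (SPRING, year + 1)
    return infer_occasions(slots)


def history_from_statuses(
    statuses,
    occasions,
    individual_id="A",
    sex="female",
    first_weight=900.0,
):
    """Build a CaptureHistory directly from a status tuple (test shorthand)."""
    detected = [i for i, s in enumerate(statuses) if s != NOT_DETECTED]
    assert detected, "history must have at least one detection"
    first, last = detected[0], detected[-1]
    occ = occasions[first]
    return CaptureHistory(
        individual_id=individual_id,
        sex=sex,
        occasions=occasions,
        statuses=tuple(statuses),
        first_detection_index=first,
        last_detection_index=last,
        first_capture_weight_g=first_weight,
        first_capture_season=occ.season,
        first_capture_year=occ.year,
    )


def make_dataset(rows, skip=(), deaths=()):
    """Dataset from compact row tuples:
    (id, season, year, night, sex, weight, newly, x, y, habitat)."""
    occasions = infer_occasions([(r[1], r[2]) for r in rows], caution=())
    lookup = {(o.season, o.year): o for o in occasions}
    events = [
        CaptureEvent(
            individual_id=r[0],
            occasion=lookup[(r[1], r[2])],
            night=r[3],
            sex=r[4] if len(r) > 4 else "female",
            weight_g=r[5] if len(r) > 5 else 900.0,
            newly_marked=r[6] if len(r) > 6 else False,
            easting_m=r[7] if len(r) > 7 else None,
            northing_m=r[8] if len(r) > 8 else None,
            zone=None,
            habitat=r[9] if len(r) > 9 else None,
        )
        for r in rows
    ]
    return Dataset(occasions=occasions, events=events, deaths=list(deaths))


@pytest.fixture
def park():
    from prickle.zones import synthetic_park

    return synthetic_park()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
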