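"""Capture-record data model, CSV dialect, validation and capture histories.

The study design this package serves is a small, closed population of
hedgehogs (*Erinaceus europaeus*) in an urban park, searched by torchlight
on two consecutive nights ("night1", "night2") each spring (May) and each
autumn (September).  Every animal caught is individually marked, weighed,
sexed and released at the capture point, whose coordinates (planar metres),
survey zone and habitat category are recorded.  In some early years extra
animals were found and marked on intervening nights during radiotracking
work; those captures carry the night label "tracking" and are handled
separately by the abundance estimators.

The CSV dialect is deliberately rigid: comma-separated, UTF-8, dot decimal,
header mandatory, columns ``individual_id, season, year, night, sex,
weight_g, newly_marked, easting_m, northing_m, zone, habitat``.  Deaths go
in a second file with columns ``individual_id, date, age_class, cause,
zone, marked``.  A survey occasion that did not happen (e.g. a spring lost
to access restrictions) is represented by its absence from the occasion
sequence, never by an occasion with zero captures.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

SPRING = "spring"
AUTUMN = "autumn"
SEASONS = (SPRING, AUTUMN)

NIGHT1 = "night1"
NIGHT2 = "night2"
TRACKING = "tracking"
NIGHTS = (NIGHT1, NIGHT2, TRACKING)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
SEXES = (MALE, FEMALE, UNKNOWN)

#: The eleven habitat categories recorded at capture sites.
HABITATS = (
    "bare artificial habitat",
    "bare soil",
    "short grass",
    "tall grass",
    "tussocky rough grassland",
    "hedgerow",
    "planted shrubbery",
    "scrub",
    "sports pitches",
    "tall herbs",
    "woodland floor",
)

DEATH_CAUSES = (
    "road",
    "predation",
    "leg_injury",
    "infection",
    "trauma",
    "drowning",
    "unknown",
)

AGE_CLASSES = ("adult", "juvenile", "unknown")

#: sanity bound on body weight in grams
MAX_WEIGHT_G = 2500.0

# per-occasion detection statuses
NOT_DETECTED = "not_detected"
NIGHT1_ONLY = "night1_only"
NIGHT2_ONLY = "night2_only"
BOTH_NIGHTS = "both_nights"
TRACKING_ONLY = "tracking_only"

CAPTURE_COLUMNS = (
    "individual_id",
    "season",
    "year",
    "night",
    "sex",
    "weight_g",
    "newly_marked",
    "easting_m",
    "northing_m",
    "zone",
    "habitat",
)

DEATH_COLUMNS = ("individual_id", "date", "age_class", "cause", "zone", "marked")


class FormatError(ValueError):
    """Raised when an input file does not conform to the documented dialect."""


class DataError(ValueError):
    """Raised when a file parses but violates dataset-level invariants."""


def season_order(season: str) -> int:
    return 0 if season == SPRING else 1


def occasion_key(season: str, year: int) -> tuple[int, int]:
    """Chronological sort key: spring precedes autumn within a year."""
    return (year, season_order(season))


@dataclass(frozen=True, order=False)
class SurveyOccasion:
    """One two-night survey: a (season, year) slot in the realized sequence.

    ``index`` is the position in the chronological sequence of occasions
    that actually took place; gaps in calendar time (a skipped survey) do
    not consume an index.  ``caution`` marks occasions whose field protocol
    deviated from the standard two-night design.
    """

    season: str
    year: int
    index: int
    caution: bool = False

    @property
    def key(self) -> tuple[int, int]:
        return occasion_key(self.season, self.year)

    @property
    def label(self) -> str:
        return f"{self.season}{self.year}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class CaptureEvent:
    """One physical capture of one marked individual on one night."""

    individual_id: str
    occasion: SurveyOccasion
    night: str
    sex: str
    weight_g: float | None = None
    newly_marked: bool = False
    easting_m: float | None = None
    northing_m: float | None = None
    zone: str | None = None
    habitat: str | None = None

    @property
    def has_coords(self) -> bool:
        return self.easting_m is not None and self.northing_m is not None


@dataclass
class DeathRecord:
    """A dead or fatally injured animal found in the park."""

    individual_id: str | None
    date: _dt.date
    age_class: str
    cause: str
    zone: str | None = None
    marked: bool = False


@dataclass
class Dataset:
    """Ordered occasions plus the capture events and deaths recorded on them."""

    occasions: tuple[SurveyOccasion, ...]
    events: list[CaptureEvent]
    deaths: list[DeathRecord] = field(default_factory=list)

    def occasion_for(self, season: str, year: int) -> SurveyOccasion | None:
        for occ in self.occasions:
            if occ.season == season and occ.year == year:
                return occ
        return None

    @property
    def individual_ids(self) -> list[str]:
        return sorted({e.individual_id for e in self.events})

    @property
    def years(self) -> list[int]:
        return sorted({occ.year for occ in self.occasions})


@dataclass
class Issue:
    """A validation finding.  Issues are data, not exceptions."""

    code: str
    individual_id: str | None
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        who = f" [{self.individual_id}]" if self.individual_id else ""
        return f"{self.code}{who}: {self.detail}"


@dataclass
class CaptureHistory:
    """Per-individual detection pattern over the realized occasion sequence.

    ``statuses[i]`` is the detection status at ``occasions[i]``.  A survey
    night detection always outranks a tracking-week one at the same
    occasion, so ``tracking_only`` means the animal was seen *only* on an
    intervening tracking night.
    """

    individual_id: str
    sex: str
    occasions: tuple[SurveyOccasion, ...]
    statuses: tuple[str, ...]
    first_detection_index: int
    last_detection_index: int
    first_capture_weight_g: float | None
    first_capture_season: str
    first_capture_year: int

    def detected_at(self, index: int) -> bool:
        return self.statuses[index] != NOT_DETECTED

    def survey_status(self, index: int) -> str:
        return self.statuses[index]

    @property
    def n_detections(self) -> int:
        return sum(1 for s in self.statuses if s != NOT_DETECTED)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_float(raw: str, *, row: int, column: str, errors: list[str]) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        errors.append(f"row {row}: column '{column}' is not a number: {raw!r}")
        return None


def _parse_bool(raw: str, *, row: int, column: str, errors: list[str]) -> bool:
    val = raw.strip().lower()
    if val in ("true", "1", "yes"):
        return True
    if val in ("false", "0", "no", ""):
        return False
    errors.append(f"row {row}: column '{column}' is not a boolean: {raw!r}")
    return False


def _parse_enum(
    raw: str, allowed: Sequence[str], *, row: int, column: str, errors: list[str]
) -> str | None:
    val = raw.strip()
    if val == "":
        return None
    if val not in allowed:
        errors.append(
            f"row {row}: column '{column}' value {raw!r} not one of {sorted(allowed)}"
        )
        return None
    return val


def infer_occasions(
    pairs: Iterable[tuple[str, int]], caution: Iterable[tuple[str, int]] = ()
) -> tuple[SurveyOccasion, ...]:
    """Build the chronologically indexed occasion sequence from (season, year) pairs."""
    caution_set = {(s, y) for s, y in caution}
    uniq = sorted(set(pairs), key=lambda p: occasion_key(*p))
    return tuple(
        SurveyOccasion(season=s, year=y, index=i, caution=(s, y) in caution_set)
        for i, (s, y) in enumerate(uniq)
    )


def read_captures(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    caution_occasions: Iterable[tuple[str, int]] = (),
) -> Dataset:
    """Read a capture CSV into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file in the documented dialect.
    column_map
        Optional mapping from the file's column names to the canonical
        ones, for adapting third-party deposits.
    caution_occasions
        (season, year) pairs whose field protocol deviated from the
        two-night standard; flagged on the occasion and carried to reports.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        rename = dict(column_map or {})
        header = [rename.get(c, c) for c in reader.fieldnames]
        missing = [c for c in CAPTURE_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        rows = []
        for raw in reader:
            rows.append({rename.get(k, k): v for k, v in raw.items() if k is not None})

    errors: list[str] = []
    parsed: list[dict] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        rec: dict = {"row": i}
        rec["individual_id"] = (row.get("individual_id") or "").strip()
        if not rec["individual_id"]:
            errors.append(f"row {i}: column 'individual_id' is empty")
        rec["season"] = _parse_enum(
            row.get("season", ""), SEASONS, row=i, column="season", errors=errors
        )
        year_raw = (row.get("year") or "").strip()
        try:
            rec["year"] = int(year_raw)
            if not 1000 <= rec["year"] <= 9999:
                raise ValueError
        except ValueError:
            errors.append(f"row {i}: column 'year' is not a 4-digit year: {year_raw!r}")
            rec["year"] = None
        rec["night"] = _parse_enum(
            row.get("night", ""), NIGHTS, row=i, column="night", errors=errors
        )
        if rec["night"] is None and not (row.get("night") or "").strip():
            errors.append(f"row {i}: column 'night' is empty")
        sex = _parse_enum(row.get("sex", ""), SEXES, row=i, column="sex", errors=errors)
        rec["sex"] = sex if sex is not None else UNKNOWN
        rec["weight_g"] = _parse_float(
            row.get("weight_g", ""), row=i, column="weight_g", errors=errors
        )
        rec["newly_marked"] = _parse_bool(
            row.get("newly_marked", ""), row=i, column="newly_marked", errors=errors
        )
        rec["easting_m"] = _parse_float(
            row.get("easting_m", ""), row=i, column="easting_m", errors=errors
        )
        rec["northing_m"] = _parse_float(
            row.get("northing_m", ""), row=i, column="northing_m", errors=errors
        )
        rec["zone"] = (row.get("zone") or "").strip() or None
        rec["habitat"] = _parse_enum(
            row.get("habitat", ""), HABITATS, row=i, column="habitat", errors=errors
        )
        parsed.append(rec)

    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))

    occasions = infer_occasions(
        ((r["season"], r["year"]) for r in parsed), caution_occasions
    )
    occ_lookup = {(o.season, o.year): o for o in occasions}

    seen: dict[tuple[str, str, int, str], int] = {}
    dups: list[str] = []
    events: list[CaptureEvent] = []
    for rec in parsed:
        key = (rec["individual_id"], rec["season"], rec["year"], rec["night"])
        if key in seen:
            dups.append(
                f"rows {seen[key]} and {rec['row']}: duplicate capture of "
                f"{rec['individual_id']} at {rec['season']}{rec['year']} {rec['night']}"
            )
        else:
            seen[key] = rec["row"]
        events.append(
            CaptureEvent(
                individual_id=rec["individual_id"],
                occasion=occ_lookup[(rec["season"], rec["year"])],
                night=rec["night"],
                sex=rec["sex"],
                weight_g=rec["weight_g"],
                newly_marked=rec["newly_marked"],
                easting_m=rec["easting_m"],
                northing_m=rec["northing_m"],
                zone=rec["zone"],
                habitat=rec["habitat"],
            )
        )
    if dups:
        raise DataError(f"{path}: " + "; ".join(dups))

    return Dataset(occasions=occasions, events=events, deaths=[])


def read_deaths(path: str | Path) -> list[DeathRecord]:
    """Read the deaths CSV (individual_id, date, age_class, cause, zone, marked)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header row required")
        missing = [c for c in DEATH_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        errors: list[str] = []
        deaths: list[DeathRecord] = []
        for i, row in enumerate(reader, start=2):
            try:
                date = _dt.date.fromisoformat((row.get("date") or "").strip())
            except ValueError:
                errors.append(f"row {i}: column 'date' is not an ISO date")
                continue
            age = _parse_enum(
                row.get("age_class", ""), AGE_CLASSES, row=i, column="age_class",
                errors=errors,
            ) or UNKNOWN
            cause = _parse_enum(
                row.get("cause", ""), DEATH_CAUSES, row=i, column="cause", errors=errors
            ) or UNKNOWN
            deaths.append(
                DeathRecord(
                    individual_id=(row.get("individual_id") or "").strip() or None,
                    date=date,
                    age_class=age,
                    cause=cause,
                    zone=(row.get("zone") or "").strip() or None,
                    marked=_parse_bool(
                        row.get("marked", ""), row=i, column="marked", errors=errors
                    ),
                )
            )
        if errors:
            raise FormatError(f"{path}: " + "; ".join(errors))
    return deaths


def _fmt_float(x: float | None) -> str:
    if x is None:
        return ""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _event_sort_key(e: CaptureEvent) -> tuple:
    return (e.occasion.index, e.individual_id, NIGHTS.index(e.night))


def write_captures(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset's events back to the dialect, deterministically ordered
    by (occasion, individual_id, night)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CAPTURE_COLUMNS)
        for e in sorted(ds.events, key=_event_sort_key):
            w.writerow(
                [
                    e.individual_id,
                    e.occasion.season,
                    e.occasion.year,
                    e.night,
                    e.sex,
                    _fmt_float(e.weight_g),
                    "true" if e.newly_marked else "false",
                    _fmt_float(e.easting_m),
                    _fmt_float(e.northing_m),
                    e.zone or "",
                    e.habitat or "",
                ]
            )


def write_deaths(deaths: Sequence[DeathRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DEATH_COLUMNS)
        for d in sorted(deaths, key=lambda d: (d.date, d.individual_id or "")):
            w.writerow(
                [
                    d.individual_id or "",
                    d.date.isoformat(),
                    d.age_class,
                    d.cause,
                    d.zone or "",
                    "true" if d.marked else "false",
                ]
            )


# ---------------------------------------------------------------------------
# validation


def validate(ds: Dataset, zone_map=None) -> list[Issue]:
    """Check dataset-level invariants; returns issues without mutating data.

    Checks: per-individual sex consistency, at most one newly_marked event
    per individual, weight sanity bounds, and (when a zone map is supplied)
    capture coordinates falling inside the declared park geometry.
    """
    issues: list[Issue] = []
    by_ind: dict[str, list[CaptureEvent]] = defaultdict(list)
    for e in ds.events:
        by_ind[e.individual_id].append(e)

    for ind in sorted(by_ind):
        events = by_ind[ind]
        sexes = {e.sex for e in events if e.sex != UNKNOWN}
        if len(sexes) > 1:
            issues.append(
                Issue("sex_conflict", ind, f"recorded as {' and '.join(sorted(sexes))}")
            )
        n_marked = sum(1 for e in events if e.newly_marked)
        if n_marked > 1:
            issues.append(
                Issue("multiple_newly_marked", ind, f"{n_marked} newly_marked events")
            )
    for e in ds.events:
        if e.weight_g is not None and not (0.0 < e.weight_g < MAX_WEIGHT_G):
            issues.append(
                Issue(
                    "weight_out_of_bounds",
                    e.individual_id,
                    f"{e.weight_g} g at {e.occasion.label} {e.night}",
                )
            )
        if zone_map is not None and e.has_coords:
            if zone_map.assign(e.easting_m, e.northing_m) == "outside":
                issues.append(
                    Issue(
                        "coords_outside_zones",
                        e.individual_id,
                        f"({e.easting_m}, {e.northing_m}) at {e.occasion.label}",
                    )
                )
    return issues


def resolve_sex(events: Sequence[CaptureEvent]) -> str:
    """Majority vote over recorded sexes; ties (and no information) -> unknown."""
    counts = Counter(e.sex for e in events if e.sex != UNKNOWN)
    if not counts:
        return UNKNOWN
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return UNKNOWN
    return top[0][0]


# ---------------------------------------------------------------------------
# capture histories


def build_histories(ds: Dataset) -> list[CaptureHistory]:
    """One :class:`CaptureHistory` per distinct individual, sorted by id.

    A survey-night detection at an occasion outranks a tracking-week one;
    the within-survey mean of recorded weights at the first detection
    occasion is stored as the first-capture weight (the field convention
    when an animal is weighed more than once within a survey).
    """
    by_ind: dict[str, list[CaptureEvent]] = defaultdict(list)
    for e in ds.events:
        by_ind[e.individual_id].append(e)

    histories: list[CaptureHistory] = []
    for ind in sorted(by_ind):
        events = by_ind[ind]
        statuses = []
        for occ in ds.occasions:
            nights = {e.night for e in events if e.occasion.index == occ.index}
            if NIGHT1 in nights and NIGHT2 in nights:
                statuses.append(BOTH_NIGHTS)
            elif NIGHT1 in nights:
                statuses.append(NIGHT1_ONLY)
            elif NIGHT2 in nights:
                statuses.append(NIGHT2_ONLY)
            elif TRACKING in nights:
                statuses.append(TRACKING_ONLY)
            else:
                statuses.append(NOT_DETECTED)
        detected = [i for i, s in enumerate(statuses) if s != NOT_DETECTED]
        first, last = detected[0], detected[-1]
        first_occ = ds.occasions[first]
        weights = [
            e.weight_g
            for e in events
            if e.occasion.index == first_occ.index and e.weight_g is not None
        ]
        first_weight = sum(weights) / len(weights) if weights else None
        histories.append(
            CaptureHistory(
                individual_id=ind,
                sex=resolve_sex(events),
                occasions=ds.occasions,
                statuses=tuple(statuses),
                first_detection_index=first,
                last_detection_index=last,
                first_capture_weight_g=first_weight,
                first_capture_season=first_occ.season,
                first_capture_year=first_occ.year,
            )
        )
    return histories
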