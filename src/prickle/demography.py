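"""Age classification, recruitment, losses, life tables and mortality summaries.

Age cannot be read from appearance in the field, so the study's convention
is a weight rule: an unmarked animal first caught in an autumn survey
weighing under 700 g is a young-of-year (juvenile); everything else is an
adult.  Juveniles age up to adults at the spring following their first
autumn, so an individual's class sequence is juvenile* then adult* and
never reverts.

"Survival" here is apparent survival: a marked animal never caught again
may have died or may simply have evaded capture; the two cannot be
distinguished by this design.  Losses are tallied per inter-survey
interval (overwinter = autumn to the following spring, over-summer =
spring to the same year's autumn) and pooled juvenile cohorts feed a
standard life table (lx, dx, Lx, Tx, ex) with ages counted in whole years
from the first autumn capture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    AUTUMN,
    FEMALE,
    MALE,
    SPRING,
    TRACKING_ONLY,
    CaptureHistory,
    Dataset,
    DeathRecord,
    SurveyOccasion,
    occasion_key,
)

logger = logging.getLogger(__name__)

ADULT = "adult"
JUVENILE = "juvenile"

#: causes treated as predation-related in mortality summaries
PREDATION_RELATED = ("predation", "leg_injury")

OVERWINTER = "overwinter"
OVERSUMMER = "oversummer"
IRREGULAR = "irregular"


@dataclass(frozen=True)
class AgeRule:
    """Weight rule separating young-of-year from adults at autumn first capture."""

    juvenile_weight_cutoff_g: float = 700.0

    def __post_init__(self) -> None:
        if self.juvenile_weight_cutoff_g <= 0:
            raise ValueError("juvenile weight cutoff must be positive")


def classify_age(
    history: CaptureHistory, occasion: SurveyOccasion, rule: AgeRule = AgeRule()
) -> str:
    """Age class of an individual at a given occasion.

    Juvenile iff the first-ever capture was in an autumn, at a weight
    strictly below the cutoff, and ``occasion`` is that same autumn.  All
    spring first captures, and every later occasion of a former juvenile,
    classify as adult.  A missing first-capture weight in autumn classifies
    (conservatively) as adult, with a warning logged.
    """
    if history.first_capture_season != AUTUMN:
        return ADULT
    w = history.first_capture_weight_g
    if w is None:
        logger.warning(
            "individual %s first caught in autumn with no weight; classed adult",
            history.individual_id,
        )
        return ADULT
    if w >= rule.juvenile_weight_cutoff_g:
        return ADULT
    if occasion.season == AUTUMN and occasion.year == history.first_capture_year:
        return JUVENILE
    return ADULT


def is_juvenile_recruit(history: CaptureHistory, rule: AgeRule = AgeRule()) -> bool:
    """True iff the individual entered the dataset as an autumn juvenile."""
    return (
        history.first_capture_season == AUTUMN
        and history.first_capture_weight_g is not None
        and history.first_capture_weight_g < rule.juvenile_weight_cutoff_g
    )


# ---------------------------------------------------------------------------
# recruitment and unmarked adults


@dataclass
class RecruitmentPoint:
    """Autumn juveniles per adult female for one year."""

    year: int
    n_juveniles: int
    n_adult_females: int
    juveniles_per_female: float | None

    @property
    def defined(self) -> bool:
        return self.juveniles_per_female is not None


def recruitment_per_female(
    histories: Sequence[CaptureHistory], rule: AgeRule = AgeRule()
) -> list[RecruitmentPoint]:
    """Juveniles captured per adult female in each autumn survey.

    Counts individuals captured at the autumn occasion (tracking-week
    captures included, matching the minimum-number-alive totals).  The
    ratio is undefined (None) in an autumn with no adult females.
    """
    if not histories:
        return []
    occasions = histories[0].occasions
    points = []
    for occ in occasions:
        if occ.season != AUTUMN:
            continue
        juv = fem = 0
        for h in histories:
            if not h.detected_at(occ.index):
                continue
            cls = classify_age(h, occ, rule)
            if cls == JUVENILE:
                juv += 1
            elif h.sex == FEMALE:
                fem += 1
        ratio = juv / fem if fem > 0 else None
        points.append(RecruitmentPoint(occ.year, juv, fem, ratio))
    return points


@dataclass
class UnmarkedAdultPoint:
    occasion: SurveyOccasion
    n_adults: int
    n_unmarked_adults: int
    pct_unmarked: float | None


def unmarked_adult_fraction(
    ds: Dataset,
    histories: Sequence[CaptureHistory] | None = None,
    rule: AgeRule = AgeRule(),
) -> list[UnmarkedAdultPoint]:
    """Per occasion: adults captured, adults newly marked, percent unmarked.

    An adult is "unmarked" at an occasion when it carries a newly_marked
    event there, i.e. it had never been caught before.  At the first
    occasion of any dataset this is 100% by construction.
    """
    from .records import build_histories

    if histories is None:
        histories = build_histories(ds)
    newly = {
        (e.individual_id, e.occasion.index) for e in ds.events if e.newly_marked
    }
    by_id = {h.individual_id: h for h in histories}
    points = []
    for occ in ds.occasions:
        adults = unmarked = 0
        for h in by_id.values():
            if not h.detected_at(occ.index):
                continue
            if classify_age(h, occ, rule) != ADULT:
                continue
            adults += 1
            if (h.individual_id, occ.index) in newly:
                unmarked += 1
        pct = 100.0 * unmarked / adults if adults > 0 else None
        points.append(UnmarkedAdultPoint(occ, adults, unmarked, pct))
    return points


# ---------------------------------------------------------------------------
# interval losses


@dataclass
class IntervalLoss:
    """Marked animals present at the interval start never recorded again.

    ``start`` and ``lost`` hold counts per class key: ``adult_male``,
    ``adult_female``, ``adult`` (all adults incl. unknown sex) and
    ``juvenile``.  ``censored`` flags the open-ended final interval, where
    "lost" cannot be separated from "outlived the study".
    """

    from_occasion: SurveyOccasion
    to_occasion: SurveyOccasion | None
    kind: str
    start: dict[str, int]
    lost: dict[str, int]
    censored: bool = False

    def pct_lost(self, key: str) -> float | None:
        n = self.start.get(key, 0)
        return 100.0 * self.lost.get(key, 0) / n if n else None


def _interval_kind(frm: SurveyOccasion, to: SurveyOccasion | None) -> str:
    if to is None:
        return OVERWINTER if frm.season == AUTUMN else OVERSUMMER
    if frm.season == AUTUMN and to.season == SPRING and to.year == frm.year + 1:
        return OVERWINTER
    if frm.season == SPRING and to.season == AUTUMN and to.year == frm.year:
        return OVERSUMMER
    return IRREGULAR


def _mna_present(h: CaptureHistory, index: int) -> bool:
    # detected at the occasion, or bracketed by earlier and later detections
    return h.detected_at(index) or (
        h.first_detection_index < index < h.last_detection_index
    )


CLASS_KEYS = ("adult_male", "adult_female", "adult", "juvenile")


def interval_losses(
    histories: Sequence[CaptureHistory],
    rule: AgeRule = AgeRule(),
    denominator: str = "mna",
) -> list[IntervalLoss]:
    """Losses per inter-survey interval, by class at the interval start.

    An individual present at occasion t is lost over (t, t+1) iff it was
    never detected at any later occasion.  ``denominator`` selects what
    counts as present: ``"mna"`` (detected, or bracketed by earlier and
    later detections — the default) or ``"captured"`` (detected at t only).
    The final interval (after the last occasion) is reported too but
    flagged right-censored.  Intervals spanning a skipped survey are
    ``irregular``.
    """
    if denominator not in ("mna", "captured"):
        raise ValueError("denominator must be 'mna' or 'captured'")
    if not histories:
        return []
    occasions = histories[0].occasions
    if len(occasions) < 2:
        raise ValueError("need at least two occasions to form intervals")
    out: list[IntervalLoss] = []
    for t, frm in enumerate(occasions):
        to = occasions[t + 1] if t + 1 < len(occasions) else None
        start = dict.fromkeys(CLASS_KEYS, 0)
        lost = dict.fromkeys(CLASS_KEYS, 0)
        for h in histories:
            present = h.detected_at(t) if denominator == "captured" else _mna_present(h, t)
            if not present:
                continue
            cls = classify_age(h, occasions[t], rule)
            if cls == JUVENILE:
                keys = ["juvenile"]
            else:
                keys = ["adult"]
                if h.sex == MALE:
                    keys.append("adult_male")
                elif h.sex == FEMALE:
                    keys.append("adult_female")
            was_lost = h.last_detection_index == t
            for k in keys:
                start[k] += 1
                if was_lost:
                    lost[k] += 1
        out.append(
            IntervalLoss(
                from_occasion=frm,
                to_occasion=to,
                kind=_interval_kind(frm, to),
                start=start,
                lost=lost,
                censored=to is None,
            )
        )
    return out


def loss_summary(
    losses: Sequence[IntervalLoss],
    first_year: int | None = None,
    last_year: int | None = None,
) -> pd.DataFrame:
    """Mean/SD of loss counts and percentages per interval kind and class.

    Regular (overwinter / over-summer) non-censored intervals whose start
    occasion falls in [first_year, last_year] are pooled; SDs use the n-1
    denominator.
    """
    rows = []
    for kind in (OVERWINTER, OVERSUMMER):
        sel = [
            l
            for l in losses
            if l.kind == kind
            and not l.censored
            and (first_year is None or l.from_occasion.year >= first_year)
            and (last_year is None or l.from_occasion.year <= last_year)
        ]
        for key in CLASS_KEYS:
            counts = [l.lost[key] for l in sel]
            pcts = [l.pct_lost(key) for l in sel if l.pct_lost(key) is not None]
            rows.append(
                {
                    "kind": kind,
                    "class": key,
                    "n_intervals": len(sel),
                    "mean_lost": float(np.mean(counts)) if counts else math.nan,
                    "sd_lost": float(np.std(counts, ddof=1))
                    if len(counts) > 1
                    else math.nan,
                    "mean_pct_lost": float(np.mean(pcts)) if pcts else math.nan,
                    "sd_pct_lost": float(np.std(pcts, ddof=1))
                    if len(pcts) > 1
                    else math.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# life tables


@dataclass
class LifeTableRow:
    """One age class of a pooled-cohort life table.

    x in whole years since the first autumn capture; lx individuals alive
    at age x; dx = lx - lx+1; Lx = (lx + lx+1)/2 animal-years lived in
    [x, x+1); Tx the tail sum of Lx; ex = Tx/lx the mean expectation of
    further life (undefined once lx = 0).
    """

    x: int
    lx: int
    dx: int
    Lx: float
    Tx: float
    ex: float | None


def life_table_from_counts(lx: Sequence[int]) -> list[LifeTableRow]:
    """Standard life-table columns from a non-increasing survivor series.

    The series is extended with a terminal zero if it does not already end
    at extinction.
    """
    counts = [int(v) for v in lx]
    if not counts:
        return []
    if any(b > a for a, b in zip(counts, counts[1:])):
        raise ValueError("survivor counts must be non-increasing")
    if counts[-1] != 0:
        counts.append(0)
    n = len(counts)
    L = [(counts[i] + counts[i + 1]) / 2.0 for i in range(n - 1)]
    rows: list[LifeTableRow] = []
    for x in range(n):
        lx_v = counts[x]
        dx = counts[x] - counts[x + 1] if x + 1 < n else 0
        Lx = L[x] if x < len(L) else 0.0
        Tx = float(sum(L[x:]))
        ex = Tx / lx_v if lx_v > 0 else None
        rows.append(LifeTableRow(x=x, lx=lx_v, dx=dx, Lx=Lx, Tx=Tx, ex=ex))
    return rows


def _age_attained(h: CaptureHistory) -> int:
    """Highest whole age (autumn anniversaries survived) supported by the
    last detection.  Spring detections extend presence but ages increment
    only at autumn occasions."""
    last = h.occasions[h.last_detection_index]
    offset = 0 if last.season == AUTUMN else 1
    return last.year - h.first_capture_year - offset


def life_table(
    histories: Sequence[CaptureHistory],
    rule: AgeRule = AgeRule(),
    cohort_years: Sequence[int] | None = None,
    sex: str | None = None,
) -> list[LifeTableRow]:
    """Pooled-cohort life table for autumn-captured juveniles.

    The cohort is every individual classified juvenile at an autumn in
    ``cohort_years`` (optionally one sex).  An individual is alive at age x
    iff it was detected at or after the autumn x years after its first
    capture.  Individuals whose age-x anniversary falls beyond the last
    survey cannot demonstrate survival, so restrict ``cohort_years`` to
    leave headroom (the callers here default to excluding the final two
    study years).
    """
    members = [
        h
        for h in histories
        if is_juvenile_recruit(h, rule)
        and (cohort_years is None or h.first_capture_year in cohort_years)
        and (sex is None or h.sex == sex)
    ]
    if not members:
        return []
    ages = [_age_attained(h) for h in members]
    max_age = max(ages)
    counts = [sum(1 for a in ages if a >= x) for x in range(max_age + 1)]
    return life_table_from_counts(counts)


def life_table_to_frame(rows: Sequence[LifeTableRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"x": r.x, "lx": r.lx, "dx": r.dx, "Lx": r.Lx, "Tx": r.Tx, "ex": r.ex}
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# weights


def weight_summary(
    ds: Dataset,
    histories: Sequence[CaptureHistory] | None = None,
    rule: AgeRule = AgeRule(),
) -> pd.DataFrame:
    """Adult body-weight summaries by sex and season.

    An animal weighed more than once within a survey contributes its
    within-survey mean once.  Rows cover each sex x season cell, each
    season pooled over sexes, each sex pooled over seasons, and the grand
    pool; SDs use the n-1 denominator.
    """
    from .records import build_histories

    if histories is None:
        histories = build_histories(ds)
    by_id = {h.individual_id: h for h in histories}

    obs: dict[tuple[str, int], list[float]] = {}
    for e in ds.events:
        if e.weight_g is None:
            continue
        obs.setdefault((e.individual_id, e.occasion.index), []).append(e.weight_g)

    records = []
    occ_by_index = {o.index: o for o in ds.occasions}
    for (ind, occ_index), weights in obs.items():
        h = by_id[ind]
        occ = occ_by_index[occ_index]
        if classify_age(h, occ, rule) != ADULT:
            continue
        records.append(
            {
                "sex": h.sex,
                "season": occ.season,
                "weight_g": sum(weights) / len(weights),
            }
        )
    df = pd.DataFrame(records, columns=["sex", "season", "weight_g"])

    def _row(sex: str, season: str, sel: pd.DataFrame) -> dict:
        return {
            "sex": sex,
            "season": season,
            "n": len(sel),
            "mean_g": float(sel["weight_g"].mean()) if len(sel) else math.nan,
            "sd_g": float(sel["weight_g"].std(ddof=1)) if len(sel) > 1 else math.nan,
        }

    rows = []
    for season in (SPRING, AUTUMN):
        for sex in (MALE, FEMALE):
            sel = df[(df.sex == sex) & (df.season == season)]
            rows.append(_row(sex, season, sel))
        rows.append(_row("all", season, df[df.season == season]))
    for sex in (MALE, FEMALE):
        rows.append(_row(sex, "all", df[df.sex == sex]))
    rows.append(_row("all", "all", df))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mortality


@dataclass
class MortalitySummary:
    """Tabulations of found deaths: cause x age class, month x age class,
    percent predation-related per age class, percent of dead that were marked."""

    by_cause: pd.DataFrame
    by_month: pd.DataFrame
    pct_predation_related: dict[str, float | None]
    pct_marked: float | None
    n_deaths: int


def mortality_tabulation(deaths: Sequence[DeathRecord]) -> MortalitySummary:
    """Summarise death records.

    Predation-related = cause in {predation, leg_injury} (leg wounds are
    attributed to predator bites).  Percentages are computed over deaths
    with a known age class and cause; the monthly histogram covers all
    dated deaths.
    """
    from .records import AGE_CLASSES, DEATH_CAUSES

    by_cause = pd.DataFrame(
        0, index=list(DEATH_CAUSES), columns=list(AGE_CLASSES), dtype=int
    )
    by_month = pd.DataFrame(
        0, index=list(range(1, 13)), columns=list(AGE_CLASSES), dtype=int
    )
    for d in deaths:
        by_cause.loc[d.cause, d.age_class] += 1
        by_month.loc[d.date.month, d.age_class] += 1

    pct_pred: dict[str, float | None] = {}
    for age in (ADULT, JUVENILE):
        known = [
            d for d in deaths if d.age_class == age and d.cause != "unknown"
        ]
        if known:
            pred = sum(1 for d in known if d.cause in PREDATION_RELATED)
            pct_pred[age] = 100.0 * pred / len(known)
        else:
            pct_pred[age] = None
    pct_marked = (
        100.0 * sum(1 for d in deaths if d.marked) / len(deaths) if deaths else None
    )
    return MortalitySummary(
        by_cause=by_cause,
        by_month=by_month,
        pct_predation_related=pct_pred,
        pct_marked=pct_marked,
        n_deaths=len(deaths),
    )
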