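"""Range centres, inter-year movements, and zone/habitat distributions.

An individual's yearly range centre is the arithmetic mean of all its
capture coordinates within a calendar year (spring, autumn and any
tracking-week captures pooled).  Displacements between consecutive-year
centres summarise park-scale movement; "long movers" are the individuals
whose displacement lies strictly above the upper quartile of all pooled
displacements.  All distances are planar Euclidean metres; quantiles
interpolate linearly between order statistics at (n+1)p plotting
positions (the exclusive-quartile convention of common spreadsheet and
Minitab-style toolchains: the upper quartile of 10, 20, 30, 40 is 37.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import HABITATS, Dataset
from .zones import OUTSIDE, ZoneMap

logger = logging.getLogger(__name__)


@dataclass
class YearlyCentre:
    """Arithmetic centre of one individual's captures in one calendar year."""

    individual_id: str
    year: int
    easting_m: float
    northing_m: float
    zone: str
    n_points: int


@dataclass
class Movement:
    """Displacement of one individual's range centre between consecutive years."""

    individual_id: str
    year_from: int
    year_to: int
    distance_m: float
    long_mover: bool = False


@dataclass
class MovementSummary:
    movements: list[Movement]
    median_m: float | None
    upper_quartile_m: float | None

    @property
    def n(self) -> int:
        return len(self.movements)

    @property
    def n_long_movers(self) -> int:
        return sum(1 for m in self.movements if m.long_mover)


def yearly_centres(ds: Dataset, zone_map: ZoneMap | None = None) -> list[YearlyCentre]:
    """Per-individual, per-calendar-year range centres.

    Events without coordinates are skipped (a count is logged).  The zone
    is assigned by point-in-polygon on the centre when a zone map is given;
    a centre inside no zone is labelled 'outside'.
    """
    groups: dict[tuple[str, int], list[tuple[float, float]]] = {}
    skipped = 0
    for e in ds.events:
        if not e.has_coords:
            skipped += 1
            continue
        groups.setdefault((e.individual_id, e.occasion.year), []).append(
            (e.easting_m, e.northing_m)
        )
    if skipped:
        logger.info("yearly_centres: skipped %d events without coordinates", skipped)
    centres = []
    for (ind, year) in sorted(groups):
        pts = groups[(ind, year)]
        x = sum(p[0] for p in pts) / len(pts)
        y = sum(p[1] for p in pts) / len(pts)
        zone = zone_map.assign(x, y) if zone_map is not None else OUTSIDE
        if zone == OUTSIDE and zone_map is not None:
            logger.info("centre of %s in %d falls outside every zone", ind, year)
        centres.append(
            YearlyCentre(
                individual_id=ind,
                year=year,
                easting_m=x,
                northing_m=y,
                zone=zone,
                n_points=len(pts),
            )
        )
    return centres


def interyear_movements(centres: Sequence[YearlyCentre]) -> MovementSummary:
    """Consecutive-year range-centre displacements, pooled across all years.

    Returns every movement with its long-mover flag (distance strictly
    greater than the pooled upper quartile), plus the pooled median and
    upper quartile ((n+1)p linear-interpolation quantiles).  With no
    consecutive-year pairs, the quantiles are None.
    """
    by_ind_year = {(c.individual_id, c.year): c for c in centres}
    movements: list[Movement] = []
    for (ind, year), c0 in sorted(by_ind_year.items()):
        c1 = by_ind_year.get((ind, year + 1))
        if c1 is None:
            continue
        d = math.hypot(c1.easting_m - c0.easting_m, c1.northing_m - c0.northing_m)
        movements.append(
            Movement(individual_id=ind, year_from=year, year_to=year + 1, distance_m=d)
        )
    if not movements:
        return MovementSummary(movements=[], median_m=None, upper_quartile_m=None)
    dists = np.array([m.distance_m for m in movements])
    median = float(np.quantile(dists, 0.5, method="weibull"))
    q3 = float(np.quantile(dists, 0.75, method="weibull"))
    for m in movements:
        m.long_mover = m.distance_m > q3
    return MovementSummary(movements=movements, median_m=median, upper_quartile_m=q3)


def zone_distribution(centres: Sequence[YearlyCentre]) -> pd.DataFrame:
    """Percent of individuals' yearly range centres per zone per year.

    Tidy frame with columns (year, zone, n, pct); the denominator for a
    year is the number of individuals with a centre that year, so
    percentages sum to 100 within each year.
    """
    rows = []
    by_year: dict[int, list[YearlyCentre]] = {}
    for c in centres:
        by_year.setdefault(c.year, []).append(c)
    for year in sorted(by_year):
        group = by_year[year]
        counts: dict[str, int] = {}
        for c in group:
            counts[c.zone] = counts.get(c.zone, 0) + 1
        for zone in sorted(counts):
            rows.append(
                {
                    "year": year,
                    "zone": zone,
                    "n": counts[zone],
                    "pct": 100.0 * counts[zone] / len(group),
                }
            )
    return pd.DataFrame(rows, columns=["year", "zone", "n", "pct"])


def habitat_distribution(ds: Dataset) -> pd.DataFrame:
    """Percent of capture events per habitat category, pooled and per year.

    Tidy frame with columns (period, habitat, n, pct) where period is
    'pooled' or a year; all 11 categories always appear (zeros included).
    Denominators count events with a non-missing habitat; if every habitat
    is missing the percentages are all zero and a warning is logged.
    """
    events = [e for e in ds.events if e.habitat is not None]
    if not events and ds.events:
        logger.warning("habitat_distribution: all events have missing habitat")

    def tally(period: str, sel) -> list[dict]:
        total = len(sel)
        counts = {h: 0 for h in HABITATS}
        for e in sel:
            counts[e.habitat] += 1
        return [
            {
                "period": period,
                "habitat": h,
                "n": counts[h],
                "pct": 100.0 * counts[h] / total if total else 0.0,
            }
            for h in HABITATS
        ]

    rows = tally("pooled", events)
    for year in ds.years:
        rows.extend(tally(str(year), [e for e in events if e.occasion.year == year]))
    return pd.DataFrame(rows, columns=["period", "habitat", "n", "pct"])
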