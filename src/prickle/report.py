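"""Analysis orchestration: run every stage and emit the report table set.

The report is the machine twin of the study's figures and tables: a
per-occasion abundance table (Chapman estimate, CI and MNA composition),
recruitment and unmarked-adult tables, interval-loss tables with pooled
means, sex-specific and pooled life tables, adult weight summaries,
mortality tabulations, zone and habitat distributions, and the movement
summary.  All tables are plain CSV and deterministic for a given dataset
and configuration; provenance (input hash, configuration echo, package
version) goes in a plain-text summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .abundance import mna_series, survey_estimates
from .demography import (
    AgeRule,
    interval_losses,
    life_table,
    life_table_to_frame,
    loss_summary,
    mortality_tabulation,
    recruitment_per_female,
    unmarked_adult_fraction,
    weight_summary,
)
from .records import FEMALE, MALE, Dataset, Issue, build_histories, validate
from .spatial import (
    habitat_distribution,
    interyear_movements,
    yearly_centres,
    zone_distribution,
)
from .zones import ZoneMap, synthetic_park

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Every analysis decision that the design leaves open, as a named key.

    ``cohort_years``: years whose autumn juveniles enter the pooled life
    table; None pools every cohort year except the final two (whose age-1
    anniversaries fall beyond the last survey).
    ``loss_summary_years``: (first, last) start-years pooled into the
    loss-summary means; None pools all regular intervals.
    ``loss_denominator``: 'mna' or 'captured' — who counts as present at an
    interval start.
    ``caution_occasions``: (season, year) pairs whose protocol deviated
    from the two-night standard; flagged in the abundance table.
    """

    juvenile_weight_cutoff_g: float = 700.0
    cohort_years: tuple[int, ...] | None = None
    loss_summary_years: tuple[int, int] | None = None
    loss_denominator: str = "mna"
    caution_occasions: tuple[tuple[str, int], ...] = ()
    column_map: dict[str, str] = field(default_factory=dict)
    zone_geojson: str | None = None

    @property
    def age_rule(self) -> AgeRule:
        return AgeRule(self.juvenile_weight_cutoff_g)

    def load_zone_map(self) -> ZoneMap:
        if self.zone_geojson:
            return ZoneMap.from_geojson(self.zone_geojson)
        return synthetic_park()

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        kw = dict(data)
        if kw.get("cohort_years") is not None:
            kw["cohort_years"] = tuple(int(y) for y in kw["cohort_years"])
        if kw.get("loss_summary_years") is not None:
            a, b = kw["loss_summary_years"]
            kw["loss_summary_years"] = (int(a), int(b))
        if kw.get("caution_occasions"):
            kw["caution_occasions"] = tuple(
                (str(s), int(y)) for s, y in kw["caution_occasions"]
            )
        return cls(**kw)


@dataclass
class AnalysisReport:
    """All output tables plus validation issues and provenance."""

    tables: dict[str, pd.DataFrame]
    issues: list[Issue]
    provenance: dict[str, object]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
        lines = ["analysis summary", "================", ""]
        for key, val in self.provenance.items():
            lines.append(f"{key}: {val}")
        lines.append(f"validation_issues: {len(self.issues)}")
        for issue in self.issues:
            lines.append(f"  - {issue}")
        (outdir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _occ_cols(occ) -> dict:
    return {"occasion": occ.label, "season": occ.season, "year": occ.year,
            "caution": occ.caution}


def analyse(
    ds: Dataset,
    config: AnalysisConfig | None = None,
    input_digest: str | None = None,
) -> AnalysisReport:
    """Run the full analysis pipeline on a validated dataset."""
    config = config or AnalysisConfig()
    rule = config.age_rule
    zone_map = config.load_zone_map()
    issues = validate(ds, zone_map=None)
    histories = build_histories(ds)

    tables: dict[str, pd.DataFrame] = {}

    ests = {e.occasion.index: e for e in survey_estimates(histories)}
    mna = mna_series(histories, rule)
    rows = []
    for pt in mna:
        est = ests[pt.occasion.index]
        rows.append(
            {
                **_occ_cols(pt.occasion),
                "n1": est.n1,
                "n2": est.n2,
                "m2": est.m2,
                "n_distinct": est.n_distinct,
                "n_hat": est.n_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "mna_total": pt.mna_total,
                "captured_in_survey": pt.captured_in_survey,
                "captured_tracking_week": pt.captured_tracking_week,
                "bridged": pt.bridged,
                "adult_male": pt.adult_male,
                "adult_female": pt.adult_female,
                "juvenile": pt.juvenile,
                "pct_adult_male": pt.pct_adult_male,
            }
        )
    tables["abundance"] = pd.DataFrame(rows)

    tables["recruitment"] = pd.DataFrame(
        [
            {
                "year": p.year,
                "n_juveniles": p.n_juveniles,
                "n_adult_females": p.n_adult_females,
                "juveniles_per_female": p.juveniles_per_female,
            }
            for p in recruitment_per_female(histories, rule)
        ]
    )

    tables["unmarked_adults"] = pd.DataFrame(
        [
            {
                **_occ_cols(p.occasion),
                "n_adults": p.n_adults,
                "n_unmarked_adults": p.n_unmarked_adults,
                "pct_unmarked": p.pct_unmarked,
            }
            for p in unmarked_adult_fraction(ds, histories, rule)
        ]
    )

    losses = interval_losses(histories, rule, denominator=config.loss_denominator)
    tables["interval_losses"] = pd.DataFrame(
        [
            {
                "from_occasion": l.from_occasion.label,
                "to_occasion": l.to_occasion.label if l.to_occasion else "",
                "kind": l.kind,
                "censored": l.censored,
                **{f"start_{k}": l.start[k] for k in l.start},
                **{f"lost_{k}": l.lost[k] for k in l.lost},
                **{f"pct_lost_{k}": l.pct_lost(k) for k in l.start},
            }
            for l in losses
        ]
    )
    if config.loss_summary_years is not None:
        y0, y1 = config.loss_summary_years
    else:
        y0 = y1 = None
    tables["loss_summary"] = loss_summary(losses, y0, y1)

    if config.cohort_years is not None:
        cohort_years: Sequence[int] = config.cohort_years
    else:
        years = ds.years
        cohort_years = years[:-2] if len(years) > 2 else years
    frames = []
    for sex, label in ((None, "pooled"), (MALE, "male"), (FEMALE, "female")):
        lt = life_table_to_frame(life_table(histories, rule, cohort_years, sex))
        if not lt.empty:
            lt.insert(0, "group", label)
            frames.append(lt)
    tables["life_table"] = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["group", "x", "lx", "dx", "Lx", "Tx", "ex"])
    )

    tables["weight_summary"] = weight_summary(ds, histories, rule)

    mort = mortality_tabulation(ds.deaths)
    tables["deaths_by_cause"] = mort.by_cause.rename_axis("cause").reset_index()
    tables["deaths_by_month"] = mort.by_month.rename_axis("month").reset_index()
    tables["mortality_summary"] = pd.DataFrame(
        [
            {
                "n_deaths": mort.n_deaths,
                "pct_predation_related_adult": mort.pct_predation_related.get("adult"),
                "pct_predation_related_juvenile": mort.pct_predation_related.get(
                    "juvenile"
                ),
                "pct_marked": mort.pct_marked,
            }
        ]
    )

    centres = yearly_centres(ds, zone_map)
    tables["zone_distribution"] = zone_distribution(centres)
    tables["habitat_distribution"] = habitat_distribution(ds)
    moves = interyear_movements(centres)
    tables["movements"] = pd.DataFrame(
        [
            {
                "individual_id": m.individual_id,
                "year_from": m.year_from,
                "year_to": m.year_to,
                "distance_m": m.distance_m,
                "long_mover": m.long_mover,
            }
            for m in moves.movements
        ]
    )
    tables["movement_summary"] = pd.DataFrame(
        [
            {
                "n_movements": moves.n,
                "median_m": moves.median_m,
                "upper_quartile_m": moves.upper_quartile_m,
                "n_long_movers": moves.n_long_movers,
            }
        ]
    )

    provenance = {
        "package_version": __version__,
        "input_sha256": input_digest or "",
        "n_occasions": len(ds.occasions),
        "n_individuals": len(histories),
        "n_events": len(ds.events),
        "n_deaths": len(ds.deaths),
        "config": yaml.safe_dump(
            dataclasses.asdict(config), default_flow_style=True
        ).strip(),
    }
    return AnalysisReport(tables=tables, issues=issues, provenance=provenance)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
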