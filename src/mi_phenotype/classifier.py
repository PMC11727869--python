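"""Per-encounter phenotype labels: MI, acute myocardial injury, or neither.

The phenotype follows the fourth universal definition's two-step logic.  An
encounter must first meet the acute-myocardial-injury troponin change
criteria; only then is ECG report evidence consulted to upgrade the label to
MI.  Which change rule applies depends on troponin availability: encounters
with two measurements within the window are judged on all within-window
pairs, the rest on the encounter's extreme values.  Encounters without two
troponin measurements are always negative, whatever their reports say.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import io as _io
from .config import RunConfig
from .ecg_nlp import EcgReport, process_report, report_is_positive
from .labs import (
    InjuryCriteria,
    InjuryEvidence,
    TroponinMeasurement,
    TroponinSeries,
    has_two_within_window,
    injury_by_encounter_extremes,
    injury_by_pairs_within_window,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeLabel",
    "Stratum",
    "EncounterClassification",
    "classify_encounter",
    "classify_frames",
    "classify_cohort",
    "classifications_to_frame",
]

CLASSIFICATION_COLUMNS = [
    "encounter_id",
    "label",
    "stratum",
    "n_troponins",
    "n_reports_retained",
    "basis",
    "qualifying_pair_values",
    "qualifying_pair_gap_hours",
    "positive_report_ids",
]


class PhenotypeLabel(str, Enum):
    MI = "MI"
    ACUTE_INJURY = "ACUTE_INJURY"
    NEITHER = "NEITHER"


class Stratum(str, Enum):
    """Troponin availability: two measurements within the serial window or not."""

    TWO_WITHIN_6H = "two_within_6h"
    NOT_TWO_WITHIN_6H = "not_two_within_6h"


@dataclass(frozen=True)
class EncounterClassification:
    """Final label for one encounter with its machine-readable evidence trail."""

    encounter_id: str
    label: PhenotypeLabel
    stratum: Stratum
    injury_evidence: InjuryEvidence
    positive_report_ids: Tuple[str, ...]
    n_troponins: int
    n_reports_retained: int

    def __post_init__(self) -> None:
        if self.label is PhenotypeLabel.MI and not (self.injury_evidence.met and self.positive_report_ids):
            raise ValueError("MI requires met injury criteria and positive ECG evidence")
        if self.label is PhenotypeLabel.ACUTE_INJURY and not self.injury_evidence.met:
            raise ValueError("ACUTE_INJURY requires met injury criteria")
        if self.n_troponins < 2 and self.label is not PhenotypeLabel.NEITHER:
            raise ValueError("fewer than two troponins must classify as NEITHER")

    def to_row(self) -> Dict[str, object]:
        pair = self.injury_evidence.qualifying_pair
        fmt = lambda v: f"{v:g}"
        return {
            "encounter_id": self.encounter_id,
            "label": self.label.value,
            "stratum": self.stratum.value,
            "n_troponins": self.n_troponins,
            "n_reports_retained": self.n_reports_retained,
            "basis": self.injury_evidence.basis,
            "qualifying_pair_values": ";".join(fmt(m.value_ngl) for m in pair) if pair else "",
            "qualifying_pair_gap_hours": (
                fmt(self.injury_evidence.gap_hours) if pair else ""
            ),
            "positive_report_ids": ";".join(self.positive_report_ids),
        }


def classify_encounter(
    series: TroponinSeries,
    reports: Sequence[EcgReport],
    criteria: InjuryCriteria,
    encounter_start: datetime,
    *,
    config: Optional[RunConfig] = None,
) -> EncounterClassification:
    """Apply the full phenotype to one encounter.

    Stratum is set by troponin availability; the matching injury rule runs
    (within-window pairs, else encounter extremes).  If injury criteria are
    unmet the label is NEITHER; if met, any retained ECG report flagging one
    of the MI-evidence patterns upgrades the label to MI, otherwise the label
    is ACUTE_INJURY.
    """
    config = config or RunConfig()
    two_within = has_two_within_window(series, criteria.window_hours)
    stratum = Stratum.TWO_WITHIN_6H if two_within else Stratum.NOT_TWO_WITHIN_6H
    if two_within:
        evidence = injury_by_pairs_within_window(series, criteria)
        if not evidence.met and config.also_check_extremes:
            evidence = injury_by_encounter_extremes(series, criteria)
    else:
        evidence = injury_by_encounter_extremes(series, criteria)

    positive_ids: List[str] = []
    n_retained = 0
    for report in reports:
        try:
            flags = process_report(
                report,
                encounter_start,
                patterns=config.patterns,
                date_formats=config.date_formats,
                body_start_marker=config.body_start_marker,
            )
        except Exception as exc:  # malformed report: skip, never fail the encounter
            logger.warning("skipping malformed report %r: %s", report.report_id, exc)
            continue
        if flags is None:
            continue
        n_retained += 1
        if report_is_positive(flags):
            positive_ids.append(report.report_id)

    if len(series) < 2 or not evidence.met:
        label = PhenotypeLabel.NEITHER
        if len(series) < 2:
            evidence = InjuryEvidence(met=False, basis="none")
    elif positive_ids:
        label = PhenotypeLabel.MI
    else:
        label = PhenotypeLabel.ACUTE_INJURY
    return EncounterClassification(
        encounter_id=series.encounter_id,
        label=label,
        stratum=stratum,
        injury_evidence=evidence,
        positive_report_ids=tuple(positive_ids),
        n_troponins=len(series),
        n_reports_retained=n_retained,
    )


def build_series_by_encounter(labs_df: pd.DataFrame) -> Dict[str, TroponinSeries]:
    """Group a parsed labs frame into per-encounter time-sorted series."""
    out: Dict[str, TroponinSeries] = {}
    for eid, grp in labs_df.groupby("encounter_id", sort=True):
        ms = [
            TroponinMeasurement(str(eid), row.taken_at.to_pydatetime(), row.raw_value, row.value_ngl)
            for row in grp.itertuples()
        ]
        out[str(eid)] = TroponinSeries.build(str(eid), ms)
    return out


def build_reports_by_encounter(reports_df: pd.DataFrame) -> Dict[str, List[EcgReport]]:
    out: Dict[str, List[EcgReport]] = {}
    for row in reports_df.itertuples():
        out.setdefault(str(row.encounter_id), []).append(
            EcgReport(
                encounter_id=str(row.encounter_id),
                reported_at=row.reported_at.to_pydatetime(),
                raw_text=row.text,
                report_id=str(row.report_id),
            )
        )
    for reports in out.values():
        reports.sort(key=lambda r: (r.reported_at, r.report_id))
    return out


def encounter_starts(
    series_by_encounter: Dict[str, TroponinSeries],
    reports_by_encounter: Dict[str, List[EcgReport]],
) -> Dict[str, datetime]:
    """Earliest observed timestamp per encounter, the admission-time proxy."""
    starts: Dict[str, datetime] = {}
    for eid, series in series_by_encounter.items():
        if len(series):
            starts[eid] = series.measurements[0].taken_at
    for eid, reports in reports_by_encounter.items():
        first = min(r.reported_at for r in reports)
        starts[eid] = min(starts.get(eid, first), first)
    return starts


def classify_frames(
    labs_df: pd.DataFrame,
    reports_df: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> List[EncounterClassification]:
    """Classify every encounter appearing in either parsed frame."""
    config = config or RunConfig()
    criteria = config.injury_criteria
    series_by_enc = build_series_by_encounter(labs_df)
    reports_by_enc = build_reports_by_encounter(reports_df)
    starts = encounter_starts(series_by_enc, reports_by_enc)
    results = []
    for eid in sorted(set(series_by_enc) | set(reports_by_enc)):
        series = series_by_enc.get(eid) or TroponinSeries(eid, ())
        results.append(
            classify_encounter(
                series,
                reports_by_enc.get(eid, []),
                criteria,
                starts[eid],
                config=config,
            )
        )
    return results


def classifications_to_frame(classifications: Sequence[EncounterClassification]) -> pd.DataFrame:
    rows = [c.to_row() for c in classifications]
    return pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)


def classify_cohort(
    labs_path: str | Path,
    reports_path: str | Path,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Read the lab and report extracts and classify the whole cohort.

    Deterministic given identical inputs and config; one output row per
    distinct encounter, sorted by encounter id.
    """
    config = config or RunConfig()
    labs_df = _io.read_labs(labs_path, config)
    reports_df = _io.read_reports(reports_path, config)
    classifications = classify_frames(labs_df, reports_df, config)
    frame = classifications_to_frame(classifications)
    counts = frame["label"].value_counts().to_dict() if len(frame) else {}
    logger.info("classified %d encounters: %s", len(frame), counts)
    return frame
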