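"""Synthetic EMR cohorts with known ground-truth phenotypes.

The real study cohorts cannot be shared, so every other module is exercised
against generated data: per-encounter troponin trajectories constructed to
realize an assigned true label under the default criteria, MUSE-style ECG
report text (header block, blank line, one finding per line), historical
yes/no/maybe labels drawn from a configurable agreement matrix, and a truth
table for round-trip checks.

Value magnitudes are drawn with guard margins around the rule thresholds
(peaks well above 14 ng/L, deltas well above or below 10 ng/L) so that
non-boundary cases are unambiguous; cases sitting exactly on a boundary are
produced separately (``boundary_fraction`` or :func:`generate_boundary_cases`).
Distractor content — header matter, "<3" values, findings cited from previous
ECGs, "age undetermined" findings, no-significant-change comparison sentences,
and entire discardable reports — is injected throughout unless disabled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Mapping, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd

from .labs import InjuryCriteria, TroponinMeasurement, TroponinSeries

__all__ = [
    "CohortSpec",
    "CohortTables",
    "BoundaryCase",
    "generate_cohort",
    "generate_boundary_cases",
    "write_cohort",
    "truth_to_historical",
]

TRUE_LABELS = ("MI", "ACUTE_INJURY", "NEITHER")
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"
_BASE = datetime(2015, 1, 1)

#: Historical-label distribution given the true phenotype, loosely shaped like
#: published phenotype-vs-diagnosis tables: diagnosed MI mostly agrees, acute
#: injury is often undiagnosed, negatives are rarely mislabelled.
DEFAULT_AGREEMENT: Dict[str, Dict[str, float]] = {
    "MI": {"yes": 0.90, "no": 0.08, "maybe": 0.02},
    "ACUTE_INJURY": {"yes": 0.30, "no": 0.68, "maybe": 0.02},
    "NEITHER": {"yes": 0.03, "no": 0.95, "maybe": 0.02},
}

_BENIGN_FINDINGS = [
    "Sinus rhythm",
    "Normal ECG",
    "Sinus bradycardia",
    "Sinus tachycardia",
    "Left axis deviation",
    "Nonspecific T wave abnormality",
    "Low voltage QRS",
    "Incomplete right bundle branch block",
]
_POSITIVE_FINDINGS = [
    "* ACUTE MI *",
    "Acute anterior infarction",
    "ST elevation, consider inferior infarction",
    "Marked ST abnormality, possible ischemia",
    "ST depression, suggests myocardial ischaemia",
]
_HEADER_LINES = [
    "Vent. rate: 84 BPM",
    "Test reason: Chest pain",
    "QRS duration: 92 ms",
    "QT/QTc: 398/442 ms",
    "BP: 132/84",
    "Technician: 1207",
]


def _fmt_date(dt: datetime) -> str:
    return dt.strftime("%d-%b-%Y").upper()


class CohortTables(NamedTuple):
    labs: pd.DataFrame
    reports: pd.DataFrame
    labels: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class CohortSpec:
    """Stated world for one synthetic cohort; same spec + seed = same cohort."""

    n_encounters: int = 2000
    seed: int = 0
    prevalence: Dict[str, float] = field(
        default_factory=lambda: {"MI": 0.3, "ACUTE_INJURY": 0.3, "NEITHER": 0.4}
    )
    p_two_within_6h: float = 0.65
    p_missing_reports: float = 0.10
    boundary_fraction: float = 0.0
    agreement_matrix: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AGREEMENT.items()}
    )
    header_lines: int = 4
    distractors: bool = True
    criteria: InjuryCriteria = field(default_factory=InjuryCriteria)

    def __post_init__(self) -> None:
        if self.n_encounters < 0:
            raise ValueError("n_encounters must be non-negative")
        if set(self.prevalence) != set(TRUE_LABELS):
            raise ValueError(f"prevalence must have keys {TRUE_LABELS}")
        if abs(sum(self.prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("prevalence must sum to 1")
        for name in ("p_two_within_6h", "p_missing_reports", "boundary_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for label in TRUE_LABELS:
            row = self.agreement_matrix.get(label)
            if row is None or set(row) != {"yes", "no", "maybe"}:
                raise ValueError(f"agreement_matrix[{label!r}] must have keys yes/no/maybe")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"agreement_matrix[{label!r}] must sum to 1")
        if self.header_lines < 0:
            raise ValueError("header_lines must be non-negative")


def _two_within(times: List[datetime], window_hours: float) -> bool:
    ts = sorted(times)
    w = timedelta(hours=window_hours)
    return any(b - a <= w for a, b in zip(ts, ts[1:]))


def _positive_troponins(
    rng: np.random.Generator, admit: datetime, within: bool, boundary: bool, spec: CohortSpec
) -> List[Tuple[datetime, str]]:
    c = spec.criteria
    t0 = admit + timedelta(minutes=int(rng.integers(30, 180)))
    if boundary:
        # exactly on every rule edge: delta == abs threshold, peak == URL,
        # gap == window (within case)
        low, high = c.url_ngl - c.abs_delta_ngl, c.url_ngl
        gap = timedelta(hours=c.window_hours) if within else timedelta(hours=30)
        return [(t0, f"{low:g}"), (t0 + gap, f"{high:g}")]
    if rng.random() < 0.3:
        low_raw, low_val = "<3", 2.0
    else:
        low_val = float(rng.integers(2, 9))
        low_raw = f"{low_val:g}"
    high_val = float(rng.integers(25, 121))
    high_raw = f"{high_val:g}"
    if within:
        gap = timedelta(minutes=int(rng.integers(60, 301)))
    else:
        gap = timedelta(minutes=int(rng.integers(8 * 60, 48 * 60)))
    rising = rng.random() < 0.7
    first, second = (low_raw, high_raw) if rising else (high_raw, low_raw)
    rows = [(t0, first), (t0 + gap, second)]
    if spec.distractors and rng.random() < 0.2:
        # an extra below-floor draw; spaced to preserve the availability stratum
        extra_t = t0 + gap / 2 if within else t0 + gap + timedelta(hours=8)
        rows.append((extra_t, "<3"))
    return sorted(rows, key=lambda r: r[0])


def _negative_troponins(
    rng: np.random.Generator, admit: datetime, boundary: bool, spec: CohortSpec
) -> List[Tuple[datetime, str]]:
    c = spec.criteria
    t0 = admit + timedelta(minutes=int(rng.integers(30, 180)))
    if boundary:
        # peak exactly at URL but delta one unit short of the threshold
        low, high = c.url_ngl - c.abs_delta_ngl + 1, c.url_ngl
        return [(t0, f"{low:g}"), (t0 + timedelta(hours=3), f"{high:g}")]
    variant = rng.choice(["single", "low_pair", "flat_pair", "none"], p=[0.3, 0.3, 0.3, 0.1])
    if variant == "none":
        return []
    if variant == "single":
        return [(t0, f"{rng.integers(16, 501)}")]
    within = rng.random() < 0.5
    gap = (
        timedelta(minutes=int(rng.integers(60, 301)))
        if within
        else timedelta(minutes=int(rng.integers(10 * 60, 30 * 60)))
    )
    if variant == "low_pair":
        # peak stays below the URL; even a "<3" companion keeps the delta < 10
        a = "<3" if (spec.distractors and rng.random() < 0.3) else f"{rng.integers(2, 12)}"
        b = f"{rng.integers(2, 12)}"
        return [(t0, a), (t0 + gap, b)]
    base = int(rng.integers(50, 301))  # flat_pair: elevated but unchanging
    delta = int(rng.integers(0, 6))
    return [(t0, f"{base}"), (t0 + gap, f"{base + delta}")]


def _render_report(
    rng: np.random.Generator,
    body_findings: List[str],
    header_lines: int,
) -> str:
    header = [_HEADER_LINES[i % len(_HEADER_LINES)] for i in range(header_lines)]
    return "\n".join(header + [""] + body_findings) if header else "\n".join(body_findings)


def _primary_report_body(
    rng: np.random.Generator,
    true_label: str,
    encounter_start: datetime,
    spec: CohortSpec,
) -> List[str]:
    n_benign = int(rng.integers(2, 5))
    idx = rng.choice(len(_BENIGN_FINDINGS), size=n_benign, replace=False)
    body = [_BENIGN_FINDINGS[i] for i in idx]
    if true_label == "MI":
        pos = _POSITIVE_FINDINGS[int(rng.integers(0, len(_POSITIVE_FINDINGS)))]
        body.insert(int(rng.integers(0, len(body) + 1)), pos)
    if spec.distractors:
        if rng.random() < 0.35:
            cited = encounter_start - timedelta(days=int(rng.integers(100, 400)))
            body.append(f"Inferior infarct (cited on or before {_fmt_date(cited)})")
        if rng.random() < 0.25:
            body.append("Anteroseptal infarct, age undetermined")
        if rng.random() < 0.25:
            # same-day comparison: removed by preprocessing, never discards
            body.append(
                f"When compared with ECG of {_fmt_date(encounter_start)} "
                f"{encounter_start:%H:%M}, No significant change was found"
            )
    return body


def _discarded_report_body(rng: np.random.Generator, encounter_start: datetime) -> List[str]:
    cited = encounter_start - timedelta(days=int(rng.integers(2, 31)))
    body = [
        f"When compared with ECG of {_fmt_date(cited)} 08:15, "
        "No significant change was found"
    ]
    if rng.random() < 0.3:
        # positive-looking content inside a discarded report must never count
        body.insert(0, _POSITIVE_FINDINGS[int(rng.integers(0, len(_POSITIVE_FINDINGS)))])
    return body


def generate_cohort(spec: CohortSpec) -> CohortTables:
    """Generate (labs, reports, labels, truth) tables realizing the spec.

    Each encounter's troponin trajectory and report content are constructed so
    that, for non-boundary cases, the default classifier provably recovers the
    assigned true label.  Timestamps are ISO 8601 strings; all randomness
    comes from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    prev = np.array([spec.prevalence[l] for l in TRUE_LABELS])
    lab_rows: List[Dict[str, str]] = []
    report_rows: List[Dict[str, str]] = []
    label_rows: List[Dict[str, str]] = []
    truth_rows: List[Dict[str, object]] = []

    for i in range(spec.n_encounters):
        eid = f"E{i:05d}"
        admit = _BASE + timedelta(
            days=int(rng.integers(0, 365)), minutes=int(rng.integers(0, 1440))
        )
        true_label = str(rng.choice(TRUE_LABELS, p=prev))
        boundary = bool(rng.random() < spec.boundary_fraction)

        if true_label == "NEITHER":
            trops = _negative_troponins(rng, admit, boundary, spec)
        else:
            within = bool(rng.random() < spec.p_two_within_6h)
            trops = _positive_troponins(rng, admit, within, boundary, spec)

        report_time = admit + timedelta(minutes=int(rng.integers(60, 1200)))
        has_report = not (rng.random() < spec.p_missing_reports)
        if true_label == "MI" or not trops:
            has_report = True  # MI needs its evidence; troponin-less encounters
            # must still appear in some input file
        event_times = [t for t, _ in trops] + ([report_time] if has_report else [])
        encounter_start = min(event_times)

        for t, raw in trops:
            lab_rows.append(
                {"encounter_id": eid, "taken_at": t.strftime(TIMESTAMP_FORMAT), "value": raw}
            )
        k = 0
        if has_report:
            body = _primary_report_body(rng, true_label, encounter_start, spec)
            report_rows.append(
                {
                    "report_id": f"{eid}-R{k}",
                    "encounter_id": eid,
                    "reported_at": report_time.strftime(TIMESTAMP_FORMAT),
                    "text": _render_report(rng, body, spec.header_lines),
                }
            )
            k += 1
        if spec.distractors and rng.random() < 0.2:
            body = _discarded_report_body(rng, encounter_start)
            t2 = report_time + timedelta(hours=2)
            report_rows.append(
                {
                    "report_id": f"{eid}-R{k}",
                    "encounter_id": eid,
                    "reported_at": t2.strftime(TIMESTAMP_FORMAT),
                    "text": _render_report(rng, body, spec.header_lines),
                }
            )

        statuses = ("yes", "no", "maybe")
        p_status = np.array([spec.agreement_matrix[true_label][s] for s in statuses])
        label_rows.append({"encounter_id": eid, "mi_status": str(rng.choice(statuses, p=p_status))})

        stratum = (
            "two_within_6h"
            if _two_within([t for t, _ in trops], spec.criteria.window_hours)
            else "not_two_within_6h"
        )
        truth_rows.append(
            {
                "encounter_id": eid,
                "true_label": true_label,
                "stratum": stratum,
                "n_troponins": len(trops),
            }
        )

    labs = pd.DataFrame(lab_rows, columns=["encounter_id", "taken_at", "value"])
    reports = pd.DataFrame(
        report_rows, columns=["report_id", "encounter_id", "reported_at", "text"]
    )
    labels = pd.DataFrame(label_rows, columns=["encounter_id", "mi_status"])
    truth = pd.DataFrame(
        truth_rows, columns=["encounter_id", "true_label", "stratum", "n_troponins"]
    )
    return CohortTables(labs, reports, labels, truth)


def truth_to_historical(truth: pd.DataFrame) -> pd.DataFrame:
    """Recode the truth table as a historical-label frame (MI/injury -> yes)."""
    status = truth["true_label"].map(
        {"MI": "yes", "ACUTE_INJURY": "yes", "NEITHER": "no"}
    )
    return pd.DataFrame({"encounter_id": truth["encounter_id"], "mi_status": status})


def write_cohort(tables: CohortTables, out_dir: str | Path) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("labs", "reports", "labels", "truth"):
        p = out / f"{name}.csv"
        getattr(tables, name).to_csv(p, index=False, lineterminator="\n")
        paths[name] = p
    return paths


@dataclass(frozen=True)
class BoundaryCase:
    """One deterministic fixture sitting exactly on a rule boundary."""

    name: str
    description: str
    series: Optional[TroponinSeries] = None
    expected_injury_met: Optional[bool] = None
    expected_basis: Optional[str] = None
    reference: Optional[float] = None
    other: Optional[float] = None
    expected_relative_met: Optional[bool] = None
    report_text: Optional[str] = None
    encounter_start: Optional[datetime] = None
    expected_discarded: Optional[bool] = None
    expected_any_flag: Optional[bool] = None


def _series(eid: str, values_at_hours: List[Tuple[float, float]]) -> TroponinSeries:
    t0 = datetime(2015, 3, 1, 8, 0)
    ms = [
        TroponinMeasurement(eid, t0 + timedelta(hours=h), f"{v:g}", float(v))
        for h, v in values_at_hours
    ]
    return TroponinSeries.build(eid, ms)


def generate_boundary_cases() -> List[BoundaryCase]:
    """Deterministic fixtures on every rule edge, for tests and documentation."""
    start = datetime(2015, 3, 1, 0, 0)
    return [
        BoundaryCase(
            name="pair_exact_boundary",
            description="delta exactly 10, peak exactly 14, gap exactly 6 h: met (inclusive)",
            series=_series("B1", [(0, 4), (6, 14)]),
            expected_injury_met=True,
            expected_basis="pair_within_window",
        ),
        BoundaryCase(
            name="peak_below_url",
            description="delta 10 but peak 13 < URL: not met",
            series=_series("B2", [(0, 3), (6, 13)]),
            expected_injury_met=False,
            expected_basis="none",
        ),
        BoundaryCase(
            name="gap_just_outside_window",
            description="qualifying values but 6.5 h apart: extremes rule applies instead",
            series=_series("B3", [(0, 4), (6.5, 14)]),
            expected_injury_met=True,
            expected_basis="encounter_extremes",
        ),
        BoundaryCase(
            name="delta_one_short",
            description="peak at URL but delta 9: not met",
            series=_series("B4", [(0, 5), (3, 14)]),
            expected_injury_met=False,
            expected_basis="none",
        ),
        BoundaryCase(
            name="relative_low_boundary",
            description="rise of exactly 50% from a reference at/below URL: strict >, not met",
            reference=10.0,
            other=15.0,
            expected_relative_met=False,
        ),
        BoundaryCase(
            name="relative_high_boundary",
            description="rise of exactly 20% from a reference above URL: strict >, not met",
            reference=20.0,
            other=24.0,
            expected_relative_met=False,
        ),
        BoundaryCase(
            name="cited_exactly_one_day",
            description="comparison ECG dated exactly 1 day before admission: retained",
            report_text=(
                "Vent. rate: 84 BPM\n\n"
                "When compared with ECG of 28-FEB-2015 00:00, No significant change was found\n"
                "Sinus rhythm"
            ),
            encounter_start=start,
            expected_discarded=False,
        ),
        BoundaryCase(
            name="cited_more_than_one_day",
            description="comparison ECG dated 10 days before admission: discarded",
            report_text=(
                "Vent. rate: 84 BPM\n\n"
                "When compared with ECG of 19-FEB-2015 08:15, No significant change was found"
            ),
            encounter_start=start,
            expected_discarded=True,
        ),
        BoundaryCase(
            name="only_removable_content",
            description="body holds only cited/age-undetermined findings: all flags false",
            report_text=(
                "Test reason: Chest pain\n\n"
                "Inferior infarct (cited on or before 01-JAN-2014)\n"
                "Anteroseptal infarct, age undetermined"
            ),
            encounter_start=start,
            expected_discarded=False,
            expected_any_flag=False,
        ),
    ]
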