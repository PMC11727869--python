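"""Rule-based NLP over free-text ECG reports.

Hospital ECG reports are auto-populated by GE's MUSE system and later edited
by physicians, which makes their language regular enough for a small set of
case-insensitive regular expressions.  Processing happens in three ordered
stages:

1. discard — a report whose only content is "no significant change" relative
   to an ECG taken more than one day before the current encounter carries no
   evidence about this encounter and is dropped whole;
2. preprocess — the header block, comparison-to-previous text, findings cited
   from previous ECGs, and "age undetermined" findings are removed so that
   stale or qualified findings cannot trigger a match;
3. flag — three patterns indicative of MI ("* acute mi", "infarc",
   "ischem|ischaem") are searched in the preprocessed body only.

Negation detection is deliberately absent: on this document type it produces
far more false positives than true positives, and a rare false MI flag is
preferred over a missed one.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

__all__ = [
    "PatternSet",
    "MUSE_PATTERNS",
    "DIALECTS",
    "DEFAULT_DATE_FORMATS",
    "EcgReport",
    "EcgFlags",
    "should_discard_report",
    "preprocess_report",
    "flag_report",
    "report_is_positive",
    "process_report",
]

#: Date dialects accepted in comparison/cited-ECG text (MUSE prints 01-JAN-1901).
DEFAULT_DATE_FORMATS: Tuple[str, ...] = ("%d-%b-%Y",)


@dataclass(frozen=True)
class PatternSet:
    """Compiled patterns for one report dialect (all case-insensitive)."""

    acute_mi: re.Pattern
    infarction: re.Pattern
    ischemia: re.Pattern
    comparison: re.Pattern
    comparison_date: re.Pattern
    no_significant_change: re.Pattern
    cited_prior: re.Pattern
    age_undetermined: re.Pattern


MUSE_PATTERNS = PatternSet(
    acute_mi=re.compile(r"\* acute mi", re.IGNORECASE),
    infarction=re.compile(r"infarc", re.IGNORECASE),
    ischemia=re.compile(r"ischem|ischaem", re.IGNORECASE),
    comparison=re.compile(r"when compared with (?:the )?ecg", re.IGNORECASE),
    comparison_date=re.compile(
        r"when compared with (?:the )?ecg of\s+(\d{1,2}-[A-Za-z]{3}-\d{4})", re.IGNORECASE
    ),
    no_significant_change=re.compile(r"no significant change", re.IGNORECASE),
    cited_prior=re.compile(r"\(cited on or before[^)]*\)", re.IGNORECASE),
    age_undetermined=re.compile(r"age undetermined", re.IGNORECASE),
)

DIALECTS = {"muse": MUSE_PATTERNS}


@dataclass
class EcgReport:
    """One free-text ECG report linked to an encounter.

    ``body`` stays empty until :func:`preprocess_report` runs; flags are never
    computed for a discarded report.
    """

    encounter_id: str
    reported_at: datetime
    raw_text: str
    report_id: str = ""
    body: str = ""
    discarded: bool = False
    discard_reason: Optional[str] = None


@dataclass(frozen=True)
class EcgFlags:
    """Per-report booleans for the three MI-evidence patterns."""

    acute_mi: bool = False
    infarction: bool = False
    ischemia: bool = False


def _parse_report_date(token: str, date_formats: Iterable[str]) -> Optional[datetime]:
    for fmt in date_formats:
        try:
            return datetime.strptime(token, fmt)
        except ValueError:
            continue
    return None


def should_discard_report(
    report: EcgReport,
    encounter_start: datetime,
    *,
    patterns: PatternSet = MUSE_PATTERNS,
    date_formats: Iterable[str] = DEFAULT_DATE_FORMATS,
) -> Tuple[bool, Optional[str]]:
    """Decide whether a report is an uninformative no-change comparison.

    True iff some line both states "no significant change" and cites a
    comparison ECG whose date precedes ``encounter_start`` by strictly more
    than one day.  Such a report tells us the patient's ECG already looked
    like this before the encounter, so it is dropped whole.  An unparseable
    comparison date retains the report with a warning.
    """
    for line in report.raw_text.splitlines():
        if not patterns.no_significant_change.search(line):
            continue
        m = patterns.comparison_date.search(line)
        if not m:
            continue
        cited = _parse_report_date(m.group(1), date_formats)
        if cited is None:
            logger.warning(
                "report %s: comparison date %r unparseable; report retained",
                report.report_id or report.encounter_id,
                m.group(1),
            )
            continue
        if encounter_start - cited > timedelta(days=1):
            return True, f"no significant change vs ECG of {m.group(1)}"
    return False, None


def preprocess_report(
    raw_text: str,
    *,
    patterns: PatternSet = MUSE_PATTERNS,
    body_start_marker: str = "",
) -> str:
    """Strip confounding text, returning the report body used for flagging.

    Four removals, in order: (1) the header block — everything up to the
    body-start marker (default: the first blank line; reports with no marker
    are taken as all body); (2) lines comparing the current ECG to previous
    ones; (3) finding lines citing previous ECGs ("(cited on or before ...)"),
    (4) finding lines qualified as "age undetermined".  Steps 3-4 drop the
    whole finding line, since the annotation qualifies the entire finding.
    Remaining lines keep their order and original casing; blank lines are
    dropped, which makes the function idempotent.
    """
    lines = raw_text.splitlines()
    body_lines = lines
    for i, line in enumerate(lines):
        if body_start_marker:
            if body_start_marker.lower() in line.lower():
                body_lines = lines[i + 1:]
                break
        elif not line.strip():
            body_lines = lines[i + 1:]
            break
    kept = []
    for line in body_lines:
        if not line.strip():
            continue
        if patterns.comparison.search(line):
            continue
        if patterns.cited_prior.search(line):
            continue
        if patterns.age_undetermined.search(line):
            continue
        kept.append(line)
    return "\n".join(kept)


def flag_report(body: str, *, patterns: PatternSet = MUSE_PATTERNS) -> EcgFlags:
    """Search the preprocessed body for the three MI-evidence patterns."""
    return EcgFlags(
        acute_mi=bool(patterns.acute_mi.search(body)),
        infarction=bool(patterns.infarction.search(body)),
        ischemia=bool(patterns.ischemia.search(body)),
    )


def report_is_positive(flags: EcgFlags) -> bool:
    """A report supports MI when any of the three patterns occurred."""
    return flags.acute_mi or flags.infarction or flags.ischemia


def process_report(
    report: EcgReport,
    encounter_start: datetime,
    *,
    patterns: PatternSet = MUSE_PATTERNS,
    date_formats: Iterable[str] = DEFAULT_DATE_FORMATS,
    body_start_marker: str = "",
) -> Optional[EcgFlags]:
    """Run discard → preprocess → flag, mutating the report in place.

    Returns the flags, or None when the report was discarded.
    """
    discarded, reason = should_discard_report(
        report, encounter_start, patterns=patterns, date_formats=date_formats
    )
    report.discarded = discarded
    report.discard_reason = reason
    if discarded:
        report.body = ""
        return None
    report.body = preprocess_report(
        report.raw_text, patterns=patterns, body_start_marker=body_start_marker
    )
    return flag_report(report.body, patterns=patterns)
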