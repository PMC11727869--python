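"""Agreement between phenotype labels and historical MI diagnoses.

Neither the phenotype nor a historical diagnosis is a gold standard, so
agreement is reported symmetrically: simple matching coefficients (fraction
of encounters on which the two label sources agree), contingency tables of
phenotype label by historical status and troponin availability, and coverage
tables showing how many encounters in each historical stratum meet each
troponin or ECG criterion.

Display rounding follows the conventions of published clinical tables —
coefficients to two decimals, percentages to one, both half-up — while the
machine-readable results keep full precision.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .classifier import PhenotypeLabel, Stratum
from .ecg_nlp import EcgReport, process_report
from .labs import (
    InjuryCriteria,
    TroponinSeries,
    has_two_within_window,
    injury_by_pairs_within_window,
    relative_change_met,
)

logger = logging.getLogger(__name__)

__all__ = [
    "round_half_up",
    "percent",
    "AgreementResult",
    "ContingencyTable",
    "simple_matching_coefficient",
    "smc_from_counts",
    "build_contingency",
    "coverage_table",
]

LABEL_ORDER = ["ACUTE_INJURY", "MI", "NEITHER"]
STATUS_ORDER = ["yes", "no", "maybe"]
STRATUM_ORDER = [Stratum.TWO_WITHIN_6H.value, Stratum.NOT_TWO_WITHIN_6H.value]


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Column percentage as displayed: 100*count/total, half-up rounded."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def _normalize_labels(values: Iterable) -> List[str]:
    return [v.value if isinstance(v, PhenotypeLabel) else str(v) for v in values]


@dataclass(frozen=True)
class AgreementResult:
    """Simple matching coefficient of phenotype vs historical labels.

    ``positive_set`` holds the phenotype labels counted as a positive call;
    agreement is (positive & yes) + (non-positive & no).  Encounters with a
    'maybe' historical status are excluded from both counts.
    """

    positive_set: FrozenSet[str]
    stratum: str
    n_agree: int
    n_total: int

    @property
    def smc(self) -> float:
        return self.n_agree / self.n_total

    @property
    def smc_rounded(self) -> float:
        return round_half_up(self.smc, 2)


def simple_matching_coefficient(
    phenotypes: pd.DataFrame,
    historical: pd.DataFrame,
    positive_set: Iterable,
    stratum_filter: Optional[str] = None,
) -> AgreementResult:
    """SMC between phenotype labels and yes/no historical diagnoses.

    ``phenotypes`` needs columns encounter_id, label and (if a stratum filter
    is used) stratum; ``historical`` needs encounter_id, mi_status.  'maybe'
    encounters are dropped before counting.
    """
    positives = frozenset(_normalize_labels(positive_set))
    unknown = positives - set(LABEL_ORDER)
    if unknown:
        raise ValueError(f"unknown phenotype label(s) in positive_set: {sorted(unknown)}")
    merged = phenotypes.merge(historical, on="encounter_id", how="inner")
    n_unmatched = len(phenotypes) + len(historical) - 2 * len(merged)
    if merged.empty:
        raise ValueError("no encounters shared between phenotype and historical labels")
    if n_unmatched:
        logger.warning("%d encounter(s) present in only one label source; ignored", n_unmatched)
    merged = merged[merged["mi_status"] != "maybe"]
    if stratum_filter is not None:
        stratum_filter = stratum_filter.value if isinstance(stratum_filter, Stratum) else stratum_filter
        merged = merged[merged["stratum"] == stratum_filter]
    if merged.empty:
        raise ValueError("no evaluable encounters after maybe-exclusion/stratum filtering")
    pheno_positive = merged["label"].isin(positives)
    hist_positive = merged["mi_status"] == "yes"
    n_agree = int((pheno_positive == hist_positive).sum())
    return AgreementResult(
        positive_set=positives,
        stratum=stratum_filter or "pooled",
        n_agree=n_agree,
        n_total=len(merged),
    )


def smc_from_counts(
    counts: Mapping[str, Mapping[str, int]],
    positive_set: Iterable,
) -> AgreementResult:
    """SMC recomputed from a printed contingency table.

    ``counts`` maps phenotype label -> historical status -> count, e.g. one
    availability stratum of a published table.  The counts are expanded to
    pseudo-encounters and fed through :func:`simple_matching_coefficient`, so
    the arithmetic path is identical to the cohort-level computation.
    """
    rows_p, rows_h, k = [], [], 0
    for label, by_status in counts.items():
        for status, n in by_status.items():
            for _ in range(int(n)):
                rows_p.append({"encounter_id": f"C{k}", "label": label})
                rows_h.append({"encounter_id": f"C{k}", "mi_status": status})
                k += 1
    return simple_matching_coefficient(
        pd.DataFrame(rows_p), pd.DataFrame(rows_h), positive_set
    )


@dataclass
class ContingencyTable:
    """Phenotype label by (historical status x availability stratum) counts.

    Columns partition the evaluated encounters; percentages are per column.
    """

    counts: pd.DataFrame

    @property
    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        out = self.counts.copy().astype(float)
        for col in out.columns:
            total = int(totals[col])
            out[col] = [percent(int(c), total) for c in self.counts[col]]
        return out

    def to_display(self) -> pd.DataFrame:
        """Counts with column percentages in parentheses, plus totals.

        Columns are flattened to "status/stratum" strings for CSV export.
        """
        pct = self.percentages
        columns = [f"{status}/{stratum}" for status, stratum in self.counts.columns]
        disp = pd.DataFrame(index=self.counts.index, columns=columns, dtype=object)
        for col, flat in zip(self.counts.columns, columns):
            disp[flat] = [
                f"{int(c)} ({p:.1f})" for c, p in zip(self.counts[col], pct[col])
            ]
        disp.loc["Total"] = [str(int(t)) for t in self.counts.sum(axis=0)]
        disp["Total"] = [str(int(t)) for t in self.counts.sum(axis=1)] + [
            str(int(self.counts.values.sum()))
        ]
        return disp


def build_contingency(phenotypes: pd.DataFrame, historical: pd.DataFrame) -> ContingencyTable:
    """Cross-tabulate phenotype labels against historical status and stratum.

    'maybe' encounters keep their own column group.  Unknown phenotype label
    or status values are a hard error.
    """
    merged = phenotypes.merge(historical, on="encounter_id", how="inner")
    bad_labels = sorted(set(merged["label"]) - set(LABEL_ORDER))
    if bad_labels:
        raise ValueError(f"unknown phenotype label(s): {bad_labels}")
    bad_status = sorted(set(merged["mi_status"]) - set(STATUS_ORDER))
    if bad_status:
        raise ValueError(f"unknown historical status value(s): {bad_status}")
    statuses = [s for s in STATUS_ORDER if s in set(merged["mi_status"])]
    columns = pd.MultiIndex.from_tuples(
        [(s, st) for s in statuses for st in STRATUM_ORDER], names=["mi_status", "stratum"]
    )
    counts = pd.DataFrame(0, index=LABEL_ORDER, columns=columns)
    grouped = merged.groupby(["label", "mi_status", "stratum"]).size()
    for (label, status, stratum), n in grouped.items():
        counts.loc[label, (status, stratum)] = int(n)
    return ContingencyTable(counts=counts)


_TROPONIN_ROWS = [
    "at_least_2_measurements",
    "two_within_window",
    "any_value_elevated",
    "relative_change_encounter",
    "absolute_change_encounter",
    "relative_change_within_window",
    "absolute_change_within_window",
]
_ECG_ROWS = [
    "at_least_one_report",
    "acute_mi_noted",
    "infarction_noted",
    "ischemia_noted",
]


def _relative_pair_within_window(series: TroponinSeries, criteria: InjuryCriteria) -> bool:
    # rise-only, chronologically earlier member as reference, one of pair >= URL
    ms = series.measurements
    for i, earlier in enumerate(ms):
        for later in ms[i + 1:]:
            if later.taken_at - earlier.taken_at > criteria.window:
                break
            if max(earlier.value_ngl, later.value_ngl) < criteria.url_ngl:
                continue
            if relative_change_met(earlier.value_ngl, later.value_ngl, criteria):
                return True
    return False


def coverage_table(
    series_by_encounter: Mapping[str, TroponinSeries],
    reports_by_encounter: Mapping[str, Sequence[EcgReport]],
    historical: pd.DataFrame,
    criteria: InjuryCriteria,
    *,
    encounter_starts: Optional[Mapping[str, object]] = None,
) -> pd.DataFrame:
    """Troponin and ECG criterion coverage per historical stratum.

    For each historical status the table counts encounters meeting: at least
    two measurements; two within the window; any value at or above the URL;
    the relative and absolute change criteria over the whole encounter and
    within the window (each requiring one value of the compared pair at or
    above the URL); having any ECG report; and each MI-evidence flag.  Flags
    are only counted on reports that survive the discard rule and
    preprocessing.  Output columns are a MultiIndex (status, n/pct).
    """
    from .classifier import encounter_starts as _starts  # avoid cycle at import time

    statuses = [s for s in STATUS_ORDER if s in set(historical["mi_status"])]
    by_status: Dict[str, List[str]] = {
        s: list(historical.loc[historical["mi_status"] == s, "encounter_id"].astype(str))
        for s in statuses
    }
    starts = dict(encounter_starts) if encounter_starts else _starts(
        dict(series_by_encounter), {k: list(v) for k, v in reports_by_encounter.items()}
    )

    abs_criteria = criteria if criteria.mode == "absolute" else InjuryCriteria(
        url_ngl=criteria.url_ngl,
        abs_delta_ngl=criteria.abs_delta_ngl,
        rel_delta_low=criteria.rel_delta_low,
        rel_delta_high=criteria.rel_delta_high,
        window_hours=criteria.window_hours,
        mode="absolute",
    )

    def encounter_hits(eid: str) -> Dict[str, bool]:
        hits = {row: False for row in _TROPONIN_ROWS + _ECG_ROWS}
        series = series_by_encounter.get(eid)
        if series is not None and len(series):
            values = series.values
            hits["at_least_2_measurements"] = len(series) >= 2
            hits["two_within_window"] = has_two_within_window(series, criteria.window_hours)
            hits["any_value_elevated"] = max(values) >= criteria.url_ngl
            if len(series) >= 2 and max(values) >= criteria.url_ngl:
                hits["relative_change_encounter"] = relative_change_met(
                    min(values), max(values), criteria
                )
            hits["absolute_change_encounter"] = (
                len(series) >= 2
                and max(values) >= criteria.url_ngl
                and max(values) - min(values) >= criteria.abs_delta_ngl
            )
            hits["relative_change_within_window"] = _relative_pair_within_window(series, criteria)
            hits["absolute_change_within_window"] = injury_by_pairs_within_window(
                series, abs_criteria
            ).met
        reports = reports_by_encounter.get(eid, [])
        if reports:
            hits["at_least_one_report"] = True
            start = starts[eid]
            for report in reports:
                flags = process_report(report, start)
                if flags is None:
                    continue
                hits["acute_mi_noted"] = hits["acute_mi_noted"] or flags.acute_mi
                hits["infarction_noted"] = hits["infarction_noted"] or flags.infarction
                hits["ischemia_noted"] = hits["ischemia_noted"] or flags.ischemia
        return hits

    columns = pd.MultiIndex.from_product([statuses, ["n", "pct"]], names=["mi_status", "stat"])
    table = pd.DataFrame(0.0, index=_TROPONIN_ROWS + _ECG_ROWS, columns=columns)
    for status, eids in by_status.items():
        tally = {row: 0 for row in _TROPONIN_ROWS + _ECG_ROWS}
        for eid in eids:
            for row, hit in encounter_hits(eid).items():
                tally[row] += int(hit)
        total = len(eids)
        for row in tally:
            table.loc[row, (status, "n")] = tally[row]
            table.loc[row, (status, "pct")] = percent(tally[row], total)
    return table
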