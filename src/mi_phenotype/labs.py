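"""Serial high-sensitivity troponin handling and the acute-injury change criteria.

Acute myocardial injury is defined by a cardiac troponin value above the
99th-percentile upper reference limit (URL) together with a rising or falling
pattern on serial measurement.  This module codes raw hs-cTnT lab strings to
ng/L, holds per-encounter measurement series, and decides whether a series
meets the change criteria — either over pairs of measurements taken within a
short window of each other, or over the extremes of the whole encounter when
no such pair exists.

Two families of change thresholds are supported: an absolute change (default
10 ng/L, with at least one value of the pair at or above the 14 ng/L URL) and
a relative change (50% when the reference value is at or below the URL, 20%
when above it).  The absolute criterion is direction-agnostic; the relative
criterion counts rises only.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Literal, Optional, Sequence, Tuple

__all__ = [
    "BELOW_FLOOR_CODE",
    "TroponinValueError",
    "TroponinMeasurement",
    "TroponinSeries",
    "InjuryCriteria",
    "InjuryEvidence",
    "parse_troponin_value",
    "has_two_within_window",
    "injury_by_pairs_within_window",
    "injury_by_encounter_extremes",
    "relative_change_met",
]

Basis = Literal["pair_within_window", "encounter_extremes", "none"]

#: ng/L assigned to the assay's "<3" below-quantification sentinel.
BELOW_FLOOR_CODE = 2.0

_BELOW_FLOOR = re.compile(r"^<\s*3$")
_ABOVE = re.compile(r"^>\s*(\d+(?:\.\d+)?)$")
_NUMERIC = re.compile(r"^\d+(?:\.\d+)?$")


class TroponinValueError(ValueError):
    """A raw lab string that cannot be coded to ng/L.

    Recoverable: callers typically drop the measurement and log the string.
    """

    def __init__(self, raw_value: str):
        self.raw_value = raw_value
        super().__init__(f"unparseable troponin value: {raw_value!r}")


def parse_troponin_value(raw_value: str) -> float:
    """Code a raw hs-cTnT result string to a numeric value in ng/L.

    The assay reports integers at or above its 3 ng/L quantification floor and
    the sentinel ``"<3"`` below it; the sentinel is coded as 2 ng/L so the
    change criteria can be evaluated numerically.  Overflow sentinels ``">N"``
    are coded as N.  Plain numeric strings parse directly.  Anything else
    (e.g. ``"HEMOLYZED"``) raises :class:`TroponinValueError`.
    """
    s = raw_value.strip().lower()
    if not s:
        raise TroponinValueError(raw_value)
    if _BELOW_FLOOR.match(s):
        return BELOW_FLOOR_CODE
    if _NUMERIC.match(s):
        return float(s)
    m = _ABOVE.match(s)
    if m:
        return float(m.group(1))
    raise TroponinValueError(raw_value)


@dataclass(frozen=True)
class TroponinMeasurement:
    """One timestamped troponin assay result, raw string plus coded ng/L."""

    encounter_id: str
    taken_at: datetime
    raw_value: str
    value_ngl: float

    def __post_init__(self) -> None:
        if self.value_ngl < 0:
            raise ValueError(f"negative troponin value: {self.value_ngl}")

    @classmethod
    def from_raw(cls, encounter_id: str, taken_at: datetime, raw_value: str) -> "TroponinMeasurement":
        return cls(encounter_id, taken_at, raw_value, parse_troponin_value(raw_value))


@dataclass(frozen=True)
class TroponinSeries:
    """All troponin measurements of one encounter, ordered by draw time."""

    encounter_id: str
    measurements: Tuple[TroponinMeasurement, ...]

    def __post_init__(self) -> None:
        for m in self.measurements:
            if m.encounter_id != self.encounter_id:
                raise ValueError(
                    f"measurement encounter {m.encounter_id!r} != series encounter {self.encounter_id!r}"
                )
        times = [m.taken_at for m in self.measurements]
        if any(a > b for a, b in zip(times, times[1:])):
            raise ValueError("measurements must be sorted by taken_at")

    @classmethod
    def build(cls, encounter_id: str, measurements: Sequence[TroponinMeasurement]) -> "TroponinSeries":
        """Construct a series, sorting measurements chronologically (stable)."""
        ordered = tuple(sorted(measurements, key=lambda m: m.taken_at))
        return cls(encounter_id, ordered)

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def values(self) -> Tuple[float, ...]:
        return tuple(m.value_ngl for m in self.measurements)


@dataclass(frozen=True)
class InjuryCriteria:
    """Thresholds defining an acute-injury troponin change.

    url_ngl:        99th-percentile upper reference limit (hs-cTnT: 14 ng/L).
    abs_delta_ngl:  absolute change threshold, ng/L.
    rel_delta_low:  relative rise required when the reference value <= URL.
    rel_delta_high: relative rise required when the reference value > URL.
    window_hours:   serial-measurement window ("within 6 h", inclusive).
    mode:           which change family the phenotype uses.
    """

    url_ngl: float = 14.0
    abs_delta_ngl: float = 10.0
    rel_delta_low: float = 0.5
    rel_delta_high: float = 0.2
    window_hours: float = 6.0
    mode: Literal["absolute", "relative"] = "absolute"

    def __post_init__(self) -> None:
        for name in ("url_ngl", "abs_delta_ngl", "rel_delta_low", "rel_delta_high", "window_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rel_delta_high >= self.rel_delta_low:
            raise ValueError("rel_delta_high must be smaller than rel_delta_low")
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"unknown mode: {self.mode!r}")

    @property
    def window(self) -> timedelta:
        return timedelta(hours=self.window_hours)


@dataclass(frozen=True)
class InjuryEvidence:
    """Outcome of an injury-criteria check, with the qualifying pair if any."""

    met: bool
    basis: Basis
    qualifying_pair: Optional[Tuple[TroponinMeasurement, TroponinMeasurement]] = None

    def __post_init__(self) -> None:
        if not self.met and self.basis != "none":
            raise ValueError("unmet evidence must have basis 'none'")
        if self.basis == "pair_within_window" and self.qualifying_pair is None:
            raise ValueError("pair_within_window evidence requires a qualifying pair")

    @property
    def gap_hours(self) -> Optional[float]:
        if self.qualifying_pair is None:
            return None
        a, b = self.qualifying_pair
        return (b.taken_at - a.taken_at).total_seconds() / 3600.0


_NOT_MET = InjuryEvidence(met=False, basis="none")


def has_two_within_window(series: TroponinSeries, window_hours: float) -> bool:
    """True iff some two distinct measurements were drawn within the window.

    The window is inclusive: a gap exactly equal to ``window_hours`` counts.
    Because the series is time-sorted, checking consecutive gaps suffices.
    """
    window = timedelta(hours=window_hours)
    ms = series.measurements
    return any(b.taken_at - a.taken_at <= window for a, b in zip(ms, ms[1:]))


def injury_by_pairs_within_window(series: TroponinSeries, criteria: InjuryCriteria) -> InjuryEvidence:
    """Absolute change criterion over all pairs within the window.

    A pair qualifies when its time gap is within ``window_hours`` (inclusive),
    at least one member is at or above the URL, and the absolute difference is
    at least ``abs_delta_ngl`` (rises and falls both count).  The reported
    qualifying pair is the first in chronological order of its earlier member,
    smaller gap breaking ties.
    """
    if criteria.mode != "absolute":
        raise ValueError("pairwise absolute criterion requires criteria.mode == 'absolute'")
    ms = series.measurements
    for i, earlier in enumerate(ms):
        for later in ms[i + 1:]:
            if later.taken_at - earlier.taken_at > criteria.window:
                break  # sorted: later pairs for this i only widen the gap
            if max(earlier.value_ngl, later.value_ngl) < criteria.url_ngl:
                continue
            if abs(later.value_ngl - earlier.value_ngl) >= criteria.abs_delta_ngl:
                return InjuryEvidence(True, "pair_within_window", (earlier, later))
    return _NOT_MET


def injury_by_encounter_extremes(series: TroponinSeries, criteria: InjuryCriteria) -> InjuryEvidence:
    """Absolute change criterion over the whole encounter's extreme values.

    Fallback for encounters without two measurements close in time: qualifies
    when the largest value is at or above the URL and exceeds the smallest by
    at least ``abs_delta_ngl``.
    """
    if criteria.mode != "absolute":
        raise ValueError("extremes criterion requires criteria.mode == 'absolute'")
    if len(series) < 2:
        return _NOT_MET
    lo = min(series.measurements, key=lambda m: m.value_ngl)
    hi = max(series.measurements, key=lambda m: m.value_ngl)
    if hi.value_ngl >= criteria.url_ngl and hi.value_ngl - lo.value_ngl >= criteria.abs_delta_ngl:
        pair = (lo, hi) if lo.taken_at <= hi.taken_at else (hi, lo)
        return InjuryEvidence(True, "encounter_extremes", pair)
    return _NOT_MET


def relative_change_met(reference: float, other: float, criteria: InjuryCriteria) -> bool:
    """Relative (rise-only) change criterion between two coded values.

    The required fractional rise is ``rel_delta_low`` when the reference value
    is at or below the URL and ``rel_delta_high`` above it; the comparison is
    strict.  The reference is the chronologically earlier value (within-window
    use) or the encounter minimum (whole-encounter use); callers additionally
    require at least one of the pair to be at or above the URL.
    """
    if reference <= 0:
        raise ValueError(f"reference troponin must be positive, got {reference}")
    threshold = criteria.rel_delta_low if reference <= criteria.url_ngl else criteria.rel_delta_high
    return (other - reference) / reference > threshold
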