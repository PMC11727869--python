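"""Flat-file readers/writers and input validation.

Input schemas mirror a minimal EMR extract: one lab row per troponin
measurement (encounter_id, taken_at, value), one report row per ECG report
(encounter_id, reported_at, text, optional report_id), and an optional
historical-label file (encounter_id, mi_status in yes/no/maybe).  Reports may
alternatively arrive as a directory of one-report-per-file plain text with a
``manifest.csv`` sidecar (encounter_id, reported_at, filename).

Unparseable troponin value strings are dropped with a logged warning (EMR
extracts contain sentinels no schema enumerates); structural problems —
missing columns, bad timestamps, invalid label values — are hard errors.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .config import RunConfig
from .labs import TroponinValueError, parse_troponin_value

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_labs",
    "read_reports",
    "read_labels",
    "write_classifications",
    "FileReport",
    "ValidationReport",
    "validate_inputs",
    "write_manifest",
]

LABS_COLUMNS = ["encounter_id", "taken_at", "value"]
REPORTS_COLUMNS = ["encounter_id", "reported_at", "text"]
LABELS_COLUMNS = ["encounter_id", "mi_status"]
VALID_STATUSES = {"yes", "no", "maybe"}


class SchemaError(ValueError):
    """An input file violating the expected schema."""


def _read_csv(path: Path, required: List[str], config: RunConfig) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, sep=config.csv_delimiter, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_timestamps(series: pd.Series, config: RunConfig, path: Path, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, format=config.timestamp_format, errors="coerce")
    if parsed.isna().any():
        rows = [int(i) + 2 for i in series.index[parsed.isna()][:10]]  # 1-based incl. header
        raise SchemaError(
            f"{path}: column {column!r} has {int(parsed.isna().sum())} timestamp(s) not matching "
            f"{config.timestamp_format!r} (first file rows: {rows})"
        )
    return parsed


def read_labs(path: str | Path, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Read a troponin extract into [encounter_id, taken_at, raw_value, value_ngl].

    Rows whose value string cannot be coded are dropped with a warning.
    """
    config = config or RunConfig()
    path = Path(path)
    df = _read_csv(path, LABS_COLUMNS, config)
    if df.empty:
        return pd.DataFrame(columns=["encounter_id", "taken_at", "raw_value", "value_ngl"])
    taken_at = _parse_timestamps(df["taken_at"], config, path, "taken_at")
    values, keep = [], []
    for i, raw in enumerate(df["value"]):
        try:
            values.append(parse_troponin_value(raw))
            keep.append(True)
        except TroponinValueError:
            logger.warning("%s row %d: dropping unparseable troponin value %r", path, i + 2, raw)
            values.append(float("nan"))
            keep.append(False)
    out = pd.DataFrame(
        {
            "encounter_id": df["encounter_id"],
            "taken_at": taken_at,
            "raw_value": df["value"],
            "value_ngl": values,
        }
    )
    return out[pd.Series(keep, index=out.index)].reset_index(drop=True)


def read_reports(path: str | Path, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Read ECG reports into [report_id, encounter_id, reported_at, text].

    ``path`` is a CSV, or a directory holding one UTF-8 text file per report
    plus a manifest.csv (encounter_id, reported_at, filename).
    """
    config = config or RunConfig()
    path = Path(path)
    if path.is_dir():
        manifest = _read_csv(path / "manifest.csv", ["encounter_id", "reported_at", "filename"], config)
        texts = [(path / fn).read_text(encoding="utf-8") for fn in manifest["filename"]]
        df = manifest.drop(columns=["filename"]).assign(text=texts)
    else:
        df = _read_csv(path, REPORTS_COLUMNS, config)
    if df.empty:
        return pd.DataFrame(columns=["report_id", "encounter_id", "reported_at", "text"])
    reported_at = _parse_timestamps(df["reported_at"], config, path, "reported_at")
    if "report_id" not in df.columns:
        df = df.assign(report_id=[f"R{i:05d}" for i in range(len(df))])
    return pd.DataFrame(
        {
            "report_id": df["report_id"],
            "encounter_id": df["encounter_id"],
            "reported_at": reported_at,
            "text": df["text"],
        }
    )


def read_labels(path: str | Path, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Read historical MI labels into [encounter_id, mi_status] (yes/no/maybe)."""
    config = config or RunConfig()
    path = Path(path)
    df = _read_csv(path, LABELS_COLUMNS, config)
    if df.empty:
        return pd.DataFrame(columns=LABELS_COLUMNS)
    status = df["mi_status"].str.strip().str.lower()
    invalid = sorted(set(status) - VALID_STATUSES)
    if invalid:
        raise SchemaError(f"{path}: invalid mi_status value(s) {invalid}; allowed: yes/no/maybe")
    dups = df["encounter_id"][df["encounter_id"].duplicated()].unique()
    if len(dups):
        raise SchemaError(f"{path}: duplicate encounter_id(s) {list(dups[:5])}")
    return pd.DataFrame({"encounter_id": df["encounter_id"], "mi_status": status})


def write_classifications(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


@dataclass
class FileReport:
    path: str
    n_rows: int = 0
    missing_columns: List[str] = field(default_factory=list)
    bad_timestamp_rows: List[int] = field(default_factory=list)
    unparseable_value_rows: List[int] = field(default_factory=list)
    invalid_status_rows: List[int] = field(default_factory=list)
    duplicate_key_rows: List[int] = field(default_factory=list)

    @property
    def hard_violations(self) -> List[str]:
        out = []
        if self.missing_columns:
            out.append(f"{self.path}: missing columns {self.missing_columns}")
        if self.bad_timestamp_rows:
            out.append(f"{self.path}: unparseable timestamps at rows {self.bad_timestamp_rows[:10]}")
        if self.invalid_status_rows:
            out.append(f"{self.path}: invalid mi_status at rows {self.invalid_status_rows[:10]}")
        if self.duplicate_key_rows:
            out.append(f"{self.path}: duplicate encounter_id at rows {self.duplicate_key_rows[:10]}")
        return out


@dataclass
class ValidationReport:
    files: Dict[str, FileReport] = field(default_factory=dict)

    @property
    def hard_violations(self) -> List[str]:
        return [v for fr in self.files.values() for v in fr.hard_violations]

    @property
    def ok(self) -> bool:
        return not self.hard_violations


def _validate_file(
    path: Path,
    required: List[str],
    ts_column: Optional[str],
    config: RunConfig,
    *,
    value_column: Optional[str] = None,
    status_column: Optional[str] = None,
    unique_key: Optional[str] = None,
) -> FileReport:
    fr = FileReport(path=str(path))
    try:
        df = pd.read_csv(path, dtype=str, sep=config.csv_delimiter, keep_default_na=False)
    except Exception as exc:  # unreadable file is a hard violation
        fr.missing_columns = [f"<unreadable: {exc}>"]
        return fr
    fr.n_rows = len(df)
    fr.missing_columns = [c for c in required if c not in df.columns]
    if fr.missing_columns or df.empty:
        return fr
    if ts_column:
        parsed = pd.to_datetime(df[ts_column], format=config.timestamp_format, errors="coerce")
        fr.bad_timestamp_rows = [int(i) + 2 for i in df.index[parsed.isna()]]
    if value_column:
        for i, raw in enumerate(df[value_column]):
            try:
                parse_troponin_value(raw)
            except TroponinValueError:
                fr.unparseable_value_rows.append(i + 2)
    if status_column:
        status = df[status_column].str.strip().str.lower()
        fr.invalid_status_rows = [int(i) + 2 for i in df.index[~status.isin(VALID_STATUSES)]]
    if unique_key:
        fr.duplicate_key_rows = [int(i) + 2 for i in df.index[df[unique_key].duplicated()]]
    return fr


def validate_inputs(
    labs_path: str | Path,
    reports_path: str | Path,
    labels_path: Optional[str | Path] = None,
    config: Optional[RunConfig] = None,
) -> ValidationReport:
    """Check input files against the expected schemas without raising.

    Returns per-file counts of rows, parse failures, bad timestamps, invalid
    statuses and duplicate keys; callers exit non-zero on hard violations.
    """
    config = config or RunConfig()
    report = ValidationReport()
    report.files["labs"] = _validate_file(
        Path(labs_path), LABS_COLUMNS, "taken_at", config, value_column="value"
    )
    rp = Path(reports_path)
    if rp.is_dir():
        report.files["reports"] = _validate_file(
            rp / "manifest.csv", ["encounter_id", "reported_at", "filename"], "reported_at", config
        )
    else:
        report.files["reports"] = _validate_file(rp, REPORTS_COLUMNS, "reported_at", config)
    if labels_path is not None:
        report.files["labels"] = _validate_file(
            Path(labels_path), LABELS_COLUMNS, None, config,
            status_column="mi_status", unique_key="encounter_id",
        )
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    inputs: Dict[str, str | Path],
    config: RunConfig,
    seed: Optional[int] = None,
) -> None:
    """Write a run manifest (input checksums, config hash, seed) next to outputs."""
    config_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest = {
        "created": datetime.now().isoformat(timespec="seconds"),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if p is not None and Path(p).is_file()
        },
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
    }
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
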