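"""Run configuration: thresholds, text-processing dialect, file dialects.

A single YAML document drives every subcommand.  Absent keys fall back to the
phenotype's published defaults (URL 14 ng/L, absolute delta 10 ng/L, relative
0.5/0.2, 6 h window, absolute mode); unknown keys are rejected by name so a
typo cannot silently run with defaults.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .ecg_nlp import DIALECTS, PatternSet
from .labs import InjuryCriteria

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "CriteriaConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class CriteriaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    url_ngl: float = 14.0
    abs_delta_ngl: float = 10.0
    rel_delta_low: float = 0.5
    rel_delta_high: float = 0.2
    window_hours: float = 6.0
    mode: Literal["absolute", "relative"] = "absolute"

    def to_criteria(self) -> InjuryCriteria:
        return InjuryCriteria(**self.model_dump())


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    criteria: CriteriaConfig = CriteriaConfig()
    #: strptime dialects accepted for dates cited inside report text
    date_formats: List[str] = ["%d-%b-%Y"]
    #: single timestamp format for all input files; mixed formats are an error
    timestamp_format: str = "%Y-%m-%dT%H:%M:%S"
    #: substring marking the last header line; empty = first blank line
    body_start_marker: str = ""
    regex_dialect: Literal["muse"] = "muse"
    csv_delimiter: str = ","
    log_level: str = "INFO"
    #: in the two-within-window stratum, also fall back to encounter extremes
    also_check_extremes: bool = False

    @property
    def injury_criteria(self) -> InjuryCriteria:
        return self.criteria.to_criteria()

    @property
    def patterns(self) -> PatternSet:
        return DIALECTS[self.regex_dialect]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; None or an empty file yields all defaults.

    Unknown keys or type mismatches raise :class:`ConfigError` naming the key.
    The full effective configuration is echoed to the log.
    """
    data = {}
    if path is not None:
        raw = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a YAML mapping, got {type(data).__name__}")
    try:
        config = RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    logger.info("effective configuration: %s", config.model_dump())
    return config
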