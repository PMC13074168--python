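"""Run configuration for the classification and simulation pipelines."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date
from pathlib import Path
from typing import Optional, Union

import yaml

#: Analysis-period defaults used in the examples and docs.
DEFAULT_WINDOW_START = date(2014, 5, 15)
DEFAULT_EXTRACTION_END = date(2023, 3, 13)


class ConfigError(ValueError):
    """Invalid run configuration."""


def _as_date(value: Union[str, date], name: str) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError:
        raise ConfigError(
            f"{name}: {value!r} is not an ISO-8601 date"
        ) from None


@dataclass
class RunConfig:
    """Everything a pipeline run needs; flags override config-file values."""

    records_path: Optional[Path] = None
    encounters_path: Optional[Path] = None
    patients_path: Optional[Path] = None
    lexicon_path: Optional[Path] = None
    window_start: date = DEFAULT_WINDOW_START
    extraction_end: date = DEFAULT_EXTRACTION_END
    window_days: int = 365
    max_transitions: int = 4
    output_dir: Path = Path(".")
    seed: int = 0

    def __post_init__(self):
        self.window_start = _as_date(self.window_start, "window_start")
        self.extraction_end = _as_date(self.extraction_end, "extraction_end")
        if self.window_days <= 0:
            raise ConfigError(
                f"window_days must be positive, got {self.window_days}"
            )
        if self.window_start >= self.extraction_end:
            raise ConfigError("window_start must precede extraction_end")
        for name in ("records_path", "encounters_path", "patients_path",
                     "lexicon_path"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.output_dir = Path(self.output_dir)

    @property
    def window(self):
        return (self.window_start, self.extraction_end)


def load_config_file(path: Union[str, Path]) -> dict:
    """Read a YAML (or plain ``key: value``) config file into a dict of
    RunConfig field overrides; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of settings")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"{path}: unknown setting(s): {', '.join(sorted(unknown))}"
        )
    return data
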