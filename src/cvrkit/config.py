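"""Run configuration: a validated, fully-serialized YAML/JSON schema.

Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import InvalidArgumentError

__all__ = [
    "ProtocolConfig", "QcConfig", "MappingConfig", "StatsConfig",
    "SubjectInput", "RunConfig", "load_config", "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    baseline_mmHg: float = 35.0
    step_mmHg: float = 10.0
    block_durations_s: list[float] = [45.0, 130.0]
    inter_block_s: float = 90.0
    lead_in_s: float = 60.0
    tail_s: float = 185.0


class QcConfig(_Strict):
    n_discard: int = 3
    max_censor: int = 9
    fd_threshold_mm: float = 0.9


class MappingConfig(_Strict):
    lag_search: bool = False
    lag_window: int = 5
    signal_floor: float | None = None
    min_breath_interval_s: float = 2.0


class StatsConfig(_Strict):
    alpha: float = 0.05
    preset: str = "standard"


class SubjectInput(_Strict):
    subject_id: str
    group: str
    visit: int = 1
    bold: str
    capno: str
    masks: str
    censor: str | None = None
    tr_s: float | None = None


class RunConfig(_Strict):
    protocol: ProtocolConfig = ProtocolConfig()
    qc: QcConfig = QcConfig()
    mapping: MappingConfig = MappingConfig()
    stats: StatsConfig = StatsConfig()
    subjects: list[SubjectInput] = []
    cohort_csv: str | None = None
    out_dir: str = "cvrkit_out"
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML or JSON run configuration, rejecting unknown keys."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise InvalidArgumentError(f"invalid config {path}: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """Stable hash of the fully-serialized configuration."""
    canon = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
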