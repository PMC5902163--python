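"""Run configuration: one validated object binding every stage's parameters.

Configs round-trip through YAML/JSON unchanged and reject unknown keys, so
a manifest plus a seed reproduces any run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "SimulateConfig",
    "PreprocessConfig",
    "DetectConfig",
    "RunConfig",
    "load_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    presets: list[str] = Field(default_factory=lambda: ["human_WT_soma", "human_MT_soma"])
    n_cells: int = 50
    duration_s: float = 600.0
    movie: bool = False


class PreprocessConfig(_Strict):
    f0_method: str = "static_percentile"
    f0_percentile: float = 20.0
    rolling_ball_radius_s: float = 60.0
    auto_drift_correct: bool = True
    drift_threshold: float = 0.1
    lowpass_hz: float | None = None


class DetectConfig(_Strict):
    k_sd: float = 3.0
    min_separation_s: float | None = None  # None: half the preset's decay tau
    min_width_s: float | None = None  # None: two frame intervals
    oscillating_min_events: int = 2


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "astroca_run"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    detect: DetectConfig = Field(default_factory=DetectConfig)
    compare_metric: str = "frequency_per_min"
    compare_test: str = "mann_whitney"


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
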