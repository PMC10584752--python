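"""Run configuration: structured files (YAML/JSON), defaults, validation.

An empty config resolves to the reference parameter set (12 time steps,
sensory noise SD 2, attention persistence 0.95, sigmoid slope 5, analysis
window 0-300 ms at 25 Hz). Unknown keys are rejected with a
nearest-key suggestion, and every run can persist its fully resolved
configuration next to its outputs so results are regenerable from
config + seed alone.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import os
from dataclasses import dataclass, field

import yaml

from .observers import AgentConfig

__all__ = ["RunConfig", "AnalysisConfig", "CampaignConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CampaignConfig:
    task: str = "discrimination"
    n_agents: int = 200
    n_trials: int = 100
    T: int = 12


@dataclass(frozen=True)
class AnalysisConfig:
    window_ms: tuple[float, float] = (0.0, 300.0)
    frame_rate_hz: float = 25.0
    trial_mean: bool = True
    centering_grouping: tuple[str, ...] = ("task", "condition_boost")
    per_subject_centering: bool = False
    split_scope: tuple[str, ...] = ("subject_id", "session_id")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    model: AgentConfig = field(default_factory=AgentConfig)
    campaign: CampaignConfig = field(default_factory=CampaignConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "."
    log_level: str = "INFO"


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            suggestion = difflib.get_close_matches(key, names, n=1)
            hint = f"; did you mean {suggestion[0]!r}?" if suggestion else ""
            raise ConfigError(f"unknown key {path + key!r}{hint}")
        f = names[key]
        if cls is RunConfig and f.name in ("model", "campaign", "analysis"):
            sub_cls = {"model": AgentConfig, "campaign": CampaignConfig,
                       "analysis": AnalysisConfig}[f.name]
            kwargs[key] = _build(sub_cls, value, f"{path}{key}.")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def load_config(path: str | os.PathLike | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML or JSON run config; absent keys fall back to defaults."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        data = {**data, **overrides}
    return _build(RunConfig, data, "")


def save_config(config: RunConfig, path: str | os.PathLike) -> None:
    """Persist the fully resolved configuration as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
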