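"""Run configuration: defaults, strict loading, lossless round-trips.

A config file (YAML or JSON) has optional sections ``display``,
``seeds``, ``stimuli``, ``engine``, ``gaze``, and ``reader``; omitted
fields take the defaults below (the standard display geometry, the
six-size font ladder, and the instrument timing).  Unknown keys are an
error so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import DisplayModel
from .stimuli import DEFAULT_TRACKING
from .trial_engine import FONT_LADDER, EngineParams, GazeParams

__all__ = ["Seeds", "StimulusConfig", "ReaderConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class Seeds:
    """Every source of randomness is funneled through these."""

    pattern: int = 0
    sentences: int = 0
    gaze: int = 0


@dataclass(frozen=True)
class StimulusConfig:
    font_file: "str | None" = None  # None -> bundled serif is discovered
    tracking: float = DEFAULT_TRACKING
    line_spacing_em: float = 1.3
    font_ladder: tuple = FONT_LADDER


@dataclass(frozen=True)
class ReaderConfig:
    """Synthetic-observer psychometric curve per viewing condition."""

    clear_midpoint: float = 0.2
    high_midpoint: float = 1.07
    medium_midpoint: float = 1.26
    low_midpoint: float = 1.48
    slope_per_logmar: float = 13.6

    def midpoints(self) -> dict:
        return {
            "clear": self.clear_midpoint,
            "high": self.high_midpoint,
            "medium": self.medium_midpoint,
            "low": self.low_midpoint,
        }


@dataclass(frozen=True)
class RunConfig:
    display: DisplayModel = field(default_factory=DisplayModel)
    seeds: Seeds = field(default_factory=Seeds)
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    engine: EngineParams = field(default_factory=EngineParams)
    gaze: GazeParams = field(default_factory=GazeParams)
    reader: ReaderConfig = field(default_factory=ReaderConfig)
    rho_max_deg: float = 45.0
    output_dir: str = "phosim_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stimuli"]["font_ladder"] = list(self.stimuli.font_ladder)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        sections = {
            "display": DisplayModel,
            "seeds": Seeds,
            "stimuli": StimulusConfig,
            "engine": EngineParams,
            "gaze": GazeParams,
            "reader": ReaderConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            sub = data.pop(name, None)
            if sub is None:
                kwargs[name] = typ()
                continue
            allowed = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} in config section "
                    f"{name!r}; allowed: {sorted(allowed)}"
                )
            if name == "stimuli" and "font_ladder" in sub:
                sub = {**sub, "font_ladder": tuple(sub["font_ladder"])}
            kwargs[name] = typ(**sub)
        for name in ("rho_max_deg", "output_dir"):
            if name in data:
                kwargs[name] = data.pop(name)
        if data:
            raise ValueError(
                f"unknown top-level config key(s): {sorted(data)}"
            )
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config, applying defaults for omitted fields."""
    p = Path(path)
    text = p.read_text()
    data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    p = Path(path)
    d = config.to_dict()
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=1))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))
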