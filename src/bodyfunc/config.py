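"""Run configuration: YAML-backed flags for decomposition, filtering, and
evaluation, with unknown keys rejected."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    #: lexicon TSV path per category name; empty -> packaged mini-lexicons
    lexicons: dict[str, str] = field(default_factory=dict)
    #: detect indented section headers (off reproduces the rigid line-initial behavior)
    sections_midline: bool = False
    headerfooter_min_page_fraction: float = 0.6
    headerfooter_edge_lines: int = 3
    #: suppress mentions inside conditional phrases
    filters_conditional: bool = True
    #: bare dates trigger HISTORICAL (over-zealous; off by default)
    history_dates_trigger: bool = False
    eval_mode: str = "entity"
    eval_matching: str = "overlap"
    seed: int = 0

    _SCHEMA = {
        "lexicons": None,
        "sections": {"midline": "sections_midline"},
        "headerfooter": {
            "min_page_fraction": "headerfooter_min_page_fraction",
            "edge_lines": "headerfooter_edge_lines",
        },
        "filters": {"conditional": "filters_conditional"},
        "history": {"dates_trigger": "history_dates_trigger"},
        "eval": {"mode": "eval_mode", "matching": "eval_matching"},
        "seed": "seed",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        for key, value in (data or {}).items():
            spec = cls._SCHEMA.get(key, "missing")
            if spec == "missing":
                raise ConfigError(f"unknown config key {key!r}")
            if key == "lexicons":
                if not isinstance(value, dict):
                    raise ConfigError("lexicons must map category -> path")
                cfg.lexicons = {str(k): str(v) for k, v in value.items()}
            elif isinstance(spec, dict):
                for sub, subval in (value or {}).items():
                    if sub not in spec:
                        raise ConfigError(f"unknown config key {key}.{sub!r}")
                    setattr(cfg, spec[sub], subval)
            else:
                setattr(cfg, spec, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_dict(self) -> dict:
        return {
            "lexicons": dict(self.lexicons),
            "sections": {"midline": self.sections_midline},
            "headerfooter": {
                "min_page_fraction": self.headerfooter_min_page_fraction,
                "edge_lines": self.headerfooter_edge_lines,
            },
            "filters": {"conditional": self.filters_conditional},
            "history": {"dates_trigger": self.history_dates_trigger},
            "eval": {"mode": self.eval_mode, "matching": self.eval_matching},
            "seed": self.seed,
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)
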