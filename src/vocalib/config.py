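"""Run configuration: YAML file with CLI-flag overrides (flags win)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Settings shared by the command-line subcommands."""

    classifier: str = "recall_biased"
    window_s: float = 15.0
    tod_lo: str = "10:00"
    tod_hi: str = "18:00"
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    output_dir: str = "vocalib_output"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Read a YAML config (if given) and apply non-None overrides on top."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        values.update(raw)
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    extra = {k: v for k, v in values.items() if k not in known}
    config = RunConfig(**{k: v for k, v in values.items() if k in known}, extra=extra)
    for key, value in overrides.items():
        if value is not None:
            setattr(config, key, value)
    return config
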