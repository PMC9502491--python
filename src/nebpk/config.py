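"""Run configuration: seeds, unit convention, iteration counts, presets."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .structural import REGIMEN_PRESETS, Regimen, parse_regimen

__all__ = ["RunConfig", "load_config", "resolve_regimens"]


@dataclass
class RunConfig:
    """Reproducibility envelope for a pipeline run.

    The unit tag documents the adopted convention (dose mg, concentration
    ng/mL, apparent volumes in 10^3 L and clearances in 10^3 L/h); it is
    recorded in outputs rather than interpreted.
    """

    seed: int = 0
    units: str = "mg|ng/mL|1e3L"
    saem_k1: int = 300
    saem_k2: int = 200
    saem_chains: int = 2
    grid_step: float = 0.05
    regimen_presets: dict[str, str] = field(default_factory=dict)
    output_dir: str = "out"

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**known)


def resolve_regimens(spec: str, config: RunConfig | None = None) -> list[Regimen]:
    """Resolve a regimen request: ``"presets"``, a preset name, or a grammar string.

    Comma-separated items may mix preset names and ``"<dose>mg q<interval>h
    x<days>d"`` strings; user-defined presets in the config take precedence.
    """
    table = dict(REGIMEN_PRESETS)
    if config is not None:
        for name, text in config.regimen_presets.items():
            table[name] = parse_regimen(text)
    if spec.strip() == "presets":
        return list(table.values())
    out = []
    for item in spec.split(","):
        item = item.strip()
        if item in table:
            out.append(table[item])
        else:
            out.append(parse_regimen(item))
    return out
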