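"""YAML preset loading for simulator and training settings."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .synthetic import SyntheticConfig
from .training import TrainConfig


@dataclass
class Preset:
    name: str
    n_nights: int
    synthetic: SyntheticConfig
    training: TrainConfig
    finetune_nights: int
    finetune: TrainConfig


def _bundled_preset_path(name: str) -> Path | None:
    base = resources.files("cardiostage") / "presets" / f"{name}.yaml"
    return Path(str(base)) if base.is_file() else None


def load_preset(name_or_path: str) -> Preset:
    """Load a bundled preset by name or any preset YAML by path."""
    path = Path(name_or_path)
    if not path.exists():
        bundled = _bundled_preset_path(name_or_path)
        if bundled is None:
            raise FileNotFoundError(
                f"no preset file or bundled preset named {name_or_path!r}")
        path = bundled
    raw = yaml.safe_load(path.read_text()) or {}
    synth = raw.get("synthetic", {})
    if "transition_matrix" in synth:
        synth["transition_matrix"] = tuple(tuple(r) for r in synth["transition_matrix"])
    for key in ("stage_mean_ibi_s", "stage_ibi_sd_s"):
        if key in synth:
            synth[key] = tuple(synth[key])
    return Preset(
        name=path.stem,
        n_nights=int(raw.get("n_nights", 4)),
        synthetic=SyntheticConfig(**synth),
        training=TrainConfig(**raw.get("training", {})),
        finetune_nights=int(raw.get("finetune_nights", 0)),
        finetune=TrainConfig(**{"freeze_encoder": True, **raw.get("finetune", {})}),
    )
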