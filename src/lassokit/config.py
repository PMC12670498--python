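"""Pipeline configuration: YAML key-value file mapped onto module configs."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .annotate import AnnotateConfig
from .massmodel import WATER_MASS, FragmentConfig
from .mining import MiningConfig
from .refactor import RefactorOptions
from .synth import SynthConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All module configurations bundled; every field is YAML-overridable."""

    fragment: FragmentConfig = field(default_factory=FragmentConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    refactor: RefactorOptions = field(default_factory=RefactorOptions)
    synth: SynthConfig = field(default_factory=SynthConfig)


_TUPLE_FIELDS = {
    "charges", "loop_window", "acceptor_offsets", "precursor_len",
    "leader_bonus_range", "sd_spacing", "nces", "scan_range",
}
_SET_FIELDS = {"starter_set", "canonical_starters", "preferred_offsets"}


def _coerce(name: str, value):
    if name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
        return tuple(value)
    if name in _SET_FIELDS:
        if isinstance(value, str):
            return frozenset(value)
        return frozenset(value)
    if name == "water_offset":
        # YAML convenience: "loss" / "none" aliases for -water / 0
        if value in ("loss", "-water"):
            return -WATER_MASS
        if value in ("none", 0, "0"):
            return 0.0
    return value


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline config; missing keys fall back to module defaults.

    The YAML layout mirrors :class:`PipelineConfig`: top-level sections
    ``fragment``, ``annotate``, ``mining``, ``refactor``, ``synth``, each a
    flat key-value mapping of that module's parameters.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    updates = {}
    for section_field in fields(PipelineConfig):
        section = data.get(section_field.name)
        if not section:
            continue
        current = getattr(cfg, section_field.name)
        valid = {f.name for f in fields(current)}
        unknown = set(section) - valid
        if unknown:
            raise ValueError(
                f"unknown {section_field.name} config keys: {sorted(unknown)}"
            )
        updates[section_field.name] = replace(
            current, **{k: _coerce(k, v) for k, v in section.items()}
        )
    unknown_sections = set(data) - {f.name for f in fields(PipelineConfig)}
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    return replace(cfg, **updates)
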