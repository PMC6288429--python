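"""Run configuration: schema, validation, defaults and round-tripping.

A run is fully described by a nested mapping (YAML or JSON) with the blocks
below; every block is optional and filled with defaults, unknown keys are
rejected with a message naming the offending key.  ``remodeling.case_id``
expands to one of the six canonical subgroup weightings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .core import CellGeometry, StimulusProtocol
from .microdomain import (
    CASE_PARAMS, RemodelingParams, SubgroupFractions, case_definition,
    compute_subgroup_fractions,
)
from .phospho import PhosphoConfig


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending key."""


@dataclass(frozen=True)
class ModelConstants:
    """Extension constants not part of the baseline model."""

    tau_casl_ms: float = 0.177
    a_rel_orphan: float = 4.0
    k_orphan_mM: float = 9.0e-4

    def __post_init__(self):
        if self.tau_casl_ms <= 0:
            raise ConfigError("tau_casl_ms must be positive")
        if self.a_rel_orphan < 0 or self.k_orphan_mM <= 0:
            raise ConfigError("orphaned-release constants must be positive")


@dataclass(frozen=True)
class ClampSettings:
    holding_mv: float = -96.7
    step_mv: float = -6.7
    step_ms: float = 500.0

    def __post_init__(self):
        if not self.holding_mv < self.step_mv:
            raise ConfigError("clamp: holding_mv must be below step_mv")
        if self.step_ms <= 0:
            raise ConfigError("clamp: step_ms must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated, default-expanded run description."""

    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    case_id: int | None = None
    fractions: SubgroupFractions | None = None
    phospho: PhosphoConfig = field(default_factory=PhosphoConfig)
    geometry: CellGeometry = field(default_factory=CellGeometry)
    constants: ModelConstants = field(default_factory=ModelConstants)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    clamp: ClampSettings = field(default_factory=ClampSettings)
    output_dir: str = "."
    output_prefix: str = "run"
    log_level: str = "INFO"

    def pack_kwargs(self) -> dict:
        return dict(tau_casl_ms=self.constants.tau_casl_ms,
                    a_rel_orphan=self.constants.a_rel_orphan,
                    k_orphan_mM=self.constants.k_orphan_mM,
                    geometry=self.geometry)

    def to_mapping(self) -> dict:
        """Serializable default-expanded form; reloading reproduces self."""
        out = {
            "remodeling": {
                "f_TT": self.remodeling.f_TT,
                "f_B2AR": self.remodeling.f_B2AR,
                "f_PDE": self.remodeling.f_PDE,
                "stimulated": self.remodeling.stimulated,
            },
            "phospho": asdict(self.phospho),
            "geometry": asdict(self.geometry),
            "constants": asdict(self.constants),
            "protocol": asdict(self.protocol),
            "clamp": asdict(self.clamp),
            "output": {"directory": self.output_dir,
                       "prefix": self.output_prefix},
            "log_level": self.log_level,
        }
        if self.case_id is not None:
            out["remodeling"]["case_id"] = self.case_id
        out["phospho"].pop("stimulated", None)
        if self.fractions is not None:
            out["fractions"] = {
                "w" + g: getattr(self.fractions, "w" + g)
                for g in "ABCDEF"}
        return out


def _build(cls, block: dict, name: str, **extra):
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"{name}: unknown key(s) {sorted(unknown)}; allowed: "
            f"{sorted(allowed)}")
    try:
        return cls(**{**block, **extra})
    except (ValueError, TypeError) as err:
        raise ConfigError(f"{name}: {err}") from err


def parse_config(mapping: dict | None) -> RunConfig:
    """Validate and default-expand a raw configuration mapping."""
    mapping = dict(mapping or {})
    known_blocks = {"remodeling", "phospho", "geometry", "constants",
                    "protocol", "clamp", "output", "log_level", "fractions"}
    unknown = set(mapping) - known_blocks
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; "
                          f"allowed: {sorted(known_blocks)}")

    rem_block = dict(mapping.get("remodeling") or {})
    case_id = rem_block.pop("case_id", None)
    stimulated = bool(rem_block.get("stimulated", False))
    fractions = None
    if case_id is not None:
        if case_id not in CASE_PARAMS:
            raise ConfigError(f"remodeling.case_id must be 1..6, "
                              f"got {case_id}")
        case = case_definition(case_id, stimulated=stimulated)
        defaults = {"f_TT": case.params.f_TT, "f_B2AR": case.params.f_B2AR,
                    "f_PDE": case.params.f_PDE}
        rem_block = {**defaults, **rem_block}
        fractions = case.fractions
    remodeling = _build(RemodelingParams, rem_block, "remodeling")

    if "fractions" in mapping:
        fr = dict(mapping["fractions"])
        fractions = _build(SubgroupFractions, fr, "fractions")

    phospho = _build(PhosphoConfig, dict(mapping.get("phospho") or {}),
                     "phospho", stimulated=remodeling.stimulated)
    geometry = _build(CellGeometry, dict(mapping.get("geometry") or {}),
                      "geometry")
    constants = _build(ModelConstants, dict(mapping.get("constants") or {}),
                       "constants")
    protocol = _build(StimulusProtocol, dict(mapping.get("protocol") or {}),
                      "protocol")
    clamp = _build(ClampSettings, dict(mapping.get("clamp") or {}), "clamp")

    out_block = dict(mapping.get("output") or {})
    unknown = set(out_block) - {"directory", "prefix"}
    if unknown:
        raise ConfigError(f"output: unknown key(s) {sorted(unknown)}")

    return RunConfig(
        remodeling=remodeling, case_id=case_id, fractions=fractions,
        phospho=phospho, geometry=geometry, constants=constants,
        protocol=protocol, clamp=clamp,
        output_dir=str(out_block.get("directory", ".")),
        output_prefix=str(out_block.get("prefix", "run")),
        log_level=str(mapping.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return parse_config(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the default-expanded configuration (YAML)."""
    Path(path).write_text(
        yaml.safe_dump(config.to_mapping(), sort_keys=True))
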