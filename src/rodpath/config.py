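"""Run configuration: a strict-schema YAML config tying the pipeline together."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic import CELL_TYPES, CONDITIONS, load_protocol

__all__ = ["RunConfig", "load_config"]

_TOP_KEYS = {"master_seed", "species", "protocol", "analysis", "output_dir"}
_ANALYSIS_KEYS = {"stages", "frequency_hz", "normalize_at", "weber_range",
                  "bg_low", "bg_high", "pool_size"}
_STAGES = ("suppression", "gain", "routing", "kinetics", "integration", "snr")


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    master_seed: int
    species: str = "primate"
    protocol: dict = dataclasses.field(default_factory=dict)
    analysis: dict = dataclasses.field(default_factory=dict)
    output_dir: str = "results"

    @property
    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | dict) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with an error naming the offending key;
    ``master_seed`` is required; analysis defaults are filled in.
    """
    if isinstance(path, dict):
        raw = dict(path)
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        try:
            raw = yaml.safe_load(p.read_text())
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            loc = f" at line {mark.line + 1}" if mark is not None else ""
            raise ConfigError(f"malformed config YAML{loc}: {e}") from e
        if raw is None:
            raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "master_seed" not in raw:
        raise ConfigError("config is missing required key 'master_seed'")
    try:
        master_seed = int(raw["master_seed"])
    except (TypeError, ValueError):
        raise ConfigError("'master_seed' must be an integer") from None

    species = raw.get("species", "primate")
    if species not in ("primate", "mouse"):
        raise ConfigError(f"unknown species {species!r} (key 'species')")

    protocol = dict(raw.get("protocol", {}))
    if protocol:
        protocol.setdefault("master_seed", master_seed)
        protocol.setdefault("species", species)
        load_protocol(protocol)  # validates keys, cell types, conditions
        for ct in protocol.get("cell_types", []):
            if ct not in CELL_TYPES:
                raise ConfigError(f"unknown cell type {ct!r} (key 'protocol.cell_types')")
        for cond in protocol.get("conditions", []):
            if cond not in CONDITIONS:
                raise ConfigError(f"unknown condition {cond!r} (key 'protocol.conditions')")

    analysis = dict(raw.get("analysis", {}))
    unknown = set(analysis) - _ANALYSIS_KEYS
    if unknown:
        raise ConfigError(f"unknown analysis key(s): {sorted(unknown)}")
    for st in analysis.get("stages", []):
        if st not in _STAGES:
            raise ConfigError(f"unknown analysis stage {st!r} (key 'analysis.stages')")
    analysis.setdefault("stages", list(_STAGES))
    analysis.setdefault("frequency_hz", 4.0)
    analysis.setdefault("normalize_at", 0.3)
    analysis.setdefault("weber_range", [3.0, 100.0])
    analysis.setdefault("pool_size", 1000)

    return RunConfig(master_seed=master_seed, species=species, protocol=protocol,
                     analysis=analysis, output_dir=str(raw.get("output_dir", "results")))
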