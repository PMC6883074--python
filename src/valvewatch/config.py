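"""Run configuration: YAML schema, validation and defaults.

A run config maps construct labels (WT, L554A L555A, ...) to a topology
plus replicate trajectories, selects analyses, and carries their
parameters.  Validation is collected-errors style: every problem in the
file is reported at once.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Construct", "RunConfig", "ConfigError", "validate_config"]

KNOWN_ANALYSES = ("flux", "density", "displacement", "geometry", "rmsf", "sasa")

DEFAULT_PARAMS: dict[str, dict] = {
    "flux": {"stride_ps": 10.0, "valve_selection": "resid 554-555 and name CA"},
    "density": {"voxel_edge": 0.1},
    "displacement": {"voxel_edge": 0.1, "dt_ps": 10.0},
    "geometry": {"pairs": ["585:CD-426:CZ"], "stride_ps": 1000.0},
    "rmsf": {"fit_selection": "name CA", "target_selection": "name CA"},
    "sasa": {"cavity_residues": [554, 555], "stride_ps": 10.0, "window_ps": 1000.0},
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


@dataclass
class Construct:
    label: str
    topology: Path
    trajectories: list[Path]


@dataclass
class RunConfig:
    constructs: list[Construct]
    analyses: dict[str, dict]          # analysis name -> parameters
    equilibration_ns: float = 25.0
    output_dir: Path = Path("valvewatch_out")
    seed: int = 0
    log_level: str = "info"
    config_hash: str = ""


def _hash_config(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Defaults: 25 ns equilibration, 10 ps flux stride.  All validation
    errors are raised together in one ConfigError.
    """
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw_text = path.read_text()
        doc = yaml.safe_load(raw_text)
    except yaml.YAMLError as exc:
        raise ConfigError([f"malformed YAML: {exc}"]) from exc
    if not isinstance(doc, dict):
        raise ConfigError(["config must be a YAML mapping"])

    constructs: list[Construct] = []
    for label, spec in (doc.get("constructs") or {}).items():
        if not isinstance(spec, dict) or "topology" not in spec:
            errors.append(f"construct {label!r}: needs 'topology' and 'trajectories'")
            continue
        topo = Path(spec["topology"])
        if not topo.exists():
            errors.append(f"construct {label!r}: topology not found: {topo}")
        trajs = [Path(p) for p in spec.get("trajectories", [])]
        if not trajs:
            errors.append(f"construct {label!r}: no trajectories listed")
        for t in trajs:
            if not t.exists():
                errors.append(f"construct {label!r}: trajectory not found: {t}")
        constructs.append(Construct(label=str(label), topology=topo, trajectories=trajs))
    if not constructs and "constructs" not in doc:
        errors.append("no constructs defined")

    eq = doc.get("equilibration_ns", 25.0)
    try:
        eq = float(eq)
        if eq < 0:
            errors.append("equilibration_ns must be >= 0")
    except (TypeError, ValueError):
        errors.append(f"equilibration_ns not a number: {eq!r}")
        eq = 25.0

    analyses_doc = doc.get("analyses", {})
    if isinstance(analyses_doc, list):
        analyses_doc = {name: {} for name in analyses_doc}
    analyses: dict[str, dict] = {}
    for name, params in (analyses_doc or {}).items():
        if name not in KNOWN_ANALYSES:
            errors.append(
                f"unknown analysis {name!r} (choose from {', '.join(KNOWN_ANALYSES)})"
            )
            continue
        merged = dict(DEFAULT_PARAMS[name])
        merged.update(params or {})
        for key in ("stride_ps", "dt_ps", "voxel_edge", "window_ps"):
            if key in merged and merged[key] is not None and float(merged[key]) <= 0:
                errors.append(f"analysis {name!r}: {key} must be > 0")
        analyses[name] = merged

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        constructs=constructs,
        analyses=analyses,
        equilibration_ns=eq,
        output_dir=Path(doc.get("output_dir", "valvewatch_out")),
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "info")),
        config_hash=_hash_config(raw_text),
    )
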