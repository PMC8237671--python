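"""YAML configuration loading and provenance records."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from . import __version__
from .adoption import (
    AdoptionCurve,
    RegimeCurvePair,
    make_gaussian_curve,
    make_linear_curve,
)
from .dynamics import DEFAULT_HORIZON, PolicyPlan
from .errors import InvalidConfigError
from .panel import PanelConfig

__all__ = [
    "load_yaml",
    "curve_from_mapping",
    "pair_from_mapping",
    "plan_from_mapping",
    "panel_config_from_mapping",
    "write_provenance",
]


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InvalidConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidConfigError(f"config root must be a mapping: {path}")
    return data


def curve_from_mapping(m: dict) -> AdoptionCurve:
    try:
        family = m["family"]
        if family == "linear":
            return make_linear_curve(m["p0"], m["p1"])
        if family == "gaussian_threshold":
            return make_gaussian_curve(m["p0"], m["p1"], m["mu"], m["sigma"])
    except KeyError as e:
        raise InvalidConfigError(f"curve spec missing key {e}") from e
    raise InvalidConfigError(f"unknown curve family {m.get('family')!r}")


def pair_from_mapping(m: dict) -> RegimeCurvePair:
    for regime in ("voluntary", "enforced"):
        if regime not in m:
            raise InvalidConfigError(f"curves block missing regime {regime!r}")
    return RegimeCurvePair(
        voluntary=curve_from_mapping(m["voluntary"]),
        enforced=curve_from_mapping(m["enforced"]),
    )


def plan_from_mapping(m: dict) -> PolicyPlan:
    try:
        return PolicyPlan(
            regime=m.get("regime", "voluntary"),
            target=m["target"],
            enforcement_capacity=m.get("capacity", 1.0),
            horizon=int(m.get("horizon", DEFAULT_HORIZON)),
        )
    except KeyError as e:
        raise InvalidConfigError(f"plan block missing key {e}") from e
    except ValueError as e:
        raise InvalidConfigError(str(e)) from e


def panel_config_from_mapping(m: dict) -> PanelConfig:
    try:
        return PanelConfig.from_dict(m)
    except (TypeError, KeyError) as e:
        raise InvalidConfigError(f"invalid panel config: {e}") from e


def write_provenance(outdir, command: str, seed, config: dict) -> Path:
    """Record the exact inputs of a run next to its outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "provenance.json"
    record = {
        "package": "vaxdyn",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
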