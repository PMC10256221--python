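"""YAML run configuration and run manifests.

A config file has two sections::

    model:            # the ten ModelParams fields
      w_s: 0.9
      ...
    experiment:       # ExperimentConfig fields; coverage maps passage -> reads
      N: 20000000
      coverage: {3: 2589, 7: 2589, 10: 2589}
      ...

Unspecified fields fall back to the dataclass defaults.  Every CLI run writes
a manifest (subcommand, config path, seed, output directory, package version,
timestamp) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .model import ExperimentConfig, ModelParams


def load_config(path) -> tuple[ModelParams, ExperimentConfig, dict]:
    """Parse a YAML config into (ModelParams, ExperimentConfig, extras)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_kw = raw.get("model", {})
    exp_kw = dict(raw.get("experiment", {}))
    if "sequenced_passages" in exp_kw:
        exp_kw["sequenced_passages"] = tuple(exp_kw["sequenced_passages"])
    params = ModelParams(**model_kw) if model_kw else None
    config = ExperimentConfig(**exp_kw)
    extras = {k: v for k, v in raw.items() if k not in ("model", "experiment")}
    return params, config, extras


def save_config(params: ModelParams | None, config: ExperimentConfig, path) -> None:
    doc = {"experiment": dataclasses.asdict(config)}
    if params is not None:
        doc["model"] = dataclasses.asdict(params)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_manifest(out_dir, subcommand: str, config_path, seed: int, **extra) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": str(config_path) if config_path else None,
        "seed": int(seed),
        "output_dir": str(out_dir),
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **extra,
    }
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
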