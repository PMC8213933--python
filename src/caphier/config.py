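"""Run configuration (YAML/JSON) and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_run_config", "write_manifest"]


@dataclass
class RunConfig:
    """Pipeline-level knobs; synthetic-data knobs live in SynthConfig."""

    seed: int = 0
    level_min: int = 2
    level_max: int = 30
    n_perm: int = 10_000
    q: float = 0.05
    tfce: bool = True
    use_fractions: bool = False     # occupancy tests on fractions vs counts
    n_boot: int = 10_000
    block_rows: int = 1024          # distance-matrix memory bound
    contrast_levels: list[int] = field(default_factory=lambda: [2])

    def validate(self) -> None:
        if self.level_min < 2:
            raise ValueError("level_min must be >= 2")
        if self.level_max < self.level_min:
            raise ValueError("level_max must be >= level_min")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")


def load_run_config(path) -> RunConfig:
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    cfg.validate()
    return cfg


def _config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, *, command: str, config, seed, artifacts,
                   extra: dict | None = None) -> Path:
    """Record what a pipeline stage produced (config hash, seed, versions)."""
    import numpy
    import scipy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config)
                  and not isinstance(config, type) else config,
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
        "artifacts": sorted(str(Path(a).relative_to(outdir))
                            if str(a).startswith(str(outdir)) else str(a)
                            for a in artifacts),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return path
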