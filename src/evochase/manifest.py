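"""Run manifests: everything needed to replay a run bit-exactly.

A manifest records the full configuration snapshot, the master seed, the
package version and SHA-256 checksums of every output file.  ``verify_replay``
re-runs the experiment from the manifest in a scratch directory and compares
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .evolution import EvolutionConfig
from .world import WorldConfig

__all__ = ["sha256_file", "config_to_dict", "config_from_dict",
           "write_manifest", "read_manifest", "verify_replay"]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_to_dict(cfg: EvolutionConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def config_from_dict(d: dict) -> EvolutionConfig:
    d = dict(d)
    world = d.pop("world", {})
    known_w = {f.name for f in dataclasses.fields(WorldConfig)}
    known_e = {f.name for f in dataclasses.fields(EvolutionConfig)} - {"world"}
    bad = (set(world) - known_w) | (set(d) - known_e)
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return EvolutionConfig(world=WorldConfig(**world), **d)


def write_manifest(run_dir: str | Path, cfg: EvolutionConfig,
                   outputs: list[str], started: str, finished: str | None = None
                   ) -> Path:
    run_dir = Path(run_dir)
    man = {
        "version": __version__,
        "seed": cfg.seed,
        "config": config_to_dict(cfg),
        "started": started,
        "finished": finished or utcnow(),
        "outputs": {name: sha256_file(run_dir / name) for name in outputs},
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(man, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def utcnow() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def verify_replay(manifest_path: str | Path, out_dir: str | Path) -> bool:
    """Re-run the experiment described by a manifest and compare checksums."""
    from .cli import run_evolve_to_dir  # deferred: cli imports this module
    man = read_manifest(manifest_path)
    cfg = config_from_dict(man["config"])
    run_evolve_to_dir(cfg, out_dir)
    out_dir = Path(out_dir)
    return all(sha256_file(out_dir / name) == digest
               for name, digest in man["outputs"].items())
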