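"""Run manifests: every output file is traceable to one manifest.

The manifest sidecar (``<out>.manifest.json``) snapshots the resolved
configuration, package version, seeds, tolerances, input digests and the
output file list, plus wall-clock metadata.  Result files themselves never
contain wall-clock data, so identical config + seed gives byte-identical
results while the manifest records when/how they were made.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_path, *, subcommand: str, config_snapshot: dict,
                   seed: int | None, inputs: list | None = None,
                   outputs: list | None = None, extra: dict | None = None) -> Path:
    """Write the manifest sidecar for a completed stage; returns its path."""
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "version": __version__,
        "config": config_snapshot,
        "rng_seed": seed,
        "inputs": {str(p): _digest(p) for p in (inputs or [])},
        "outputs": [str(p) for p in (outputs or [])],
        "wall_clock_utc": datetime.now(timezone.utc).isoformat(),
        "platform": platform.platform(),
    }
    if extra:
        manifest.update(extra)
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def dump_result_json(path, payload: dict) -> None:
    """Deterministic result serialization: sorted keys, no timestamps."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
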