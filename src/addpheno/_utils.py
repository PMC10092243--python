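"""Small shared helpers: deterministic seed derivation and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed via SHA-256.

    ``stage_seed(s, name) = sha256(f"{s}:{name}") mod 2**31`` — stable across
    platforms and Python versions, unlike ``hash()``.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def write_manifest(out_dir: str | Path, config: dict, inputs: dict | None = None) -> Path:
    """Write a run manifest (config echo, seeds, input digests) as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "config": config,
        "inputs": inputs or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
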