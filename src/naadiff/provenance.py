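"""Run-log provenance records: every CLI stage appends one JSON record with
the stage name, parameters, seed, and SHA-256 hashes of its file inputs."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

__all__ = ["file_hash", "record_run"]


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def record_run(
    out_dir: str | Path,
    stage: str,
    params: dict,
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Append a provenance record to ``<out_dir>/run_log.jsonl``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = {
        "stage": stage,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "params": params,
        "inputs": {
            str(p): file_hash(p) for p in (inputs or []) if Path(p).is_file()
        },
    }
    log = out_dir / "run_log.jsonl"
    with open(log, "a") as fh:
        fh.write(json.dumps(rec, default=str) + "\n")
    return log
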