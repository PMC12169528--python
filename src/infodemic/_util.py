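"""Seed forking and provenance helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path


def fork_seed(seed: int, label: str) -> int:
    """Derive a stable per-stage seed (< 2^31) from a run seed and a label.

    Stage-level reruns then reproduce the corresponding slice of a full
    pipeline run, independent of stage order.
    """
    digest = hashlib.blake2b(
        f"{seed}:{label}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance(params: dict, inputs: dict | None = None) -> dict:
    """A machine-readable record of what produced an artifact."""
    from . import __version__

    record = {
        "tool": "infodemic",
        "version": __version__,
        "params": params,
    }
    if inputs:
        record["inputs"] = {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in inputs.items()
            if p is not None
        }
    return record


def write_provenance(path, params: dict, inputs: dict | None = None) -> None:
    Path(path).write_text(
        json.dumps(provenance(params, inputs), indent=2, sort_keys=True) + "\n"
    )


def read_flat_config(path) -> dict:
    """Flat ``key = value`` config lines; '#' comments ignored."""
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        if "=" not in body:
            raise ValueError(f"{path} line {lineno}: expected 'key = value'")
        key, value = body.split("=", 1)
        out[key.strip()] = value.strip()
    return out
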