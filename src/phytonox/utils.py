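"""Small shared helpers: seed derivation and file hashing."""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path

MAX_SEED = 2**31 - 1


def derive_seed(global_seed: int, stage: str) -> int:
    """Expand one global seed into a stable per-stage seed.

    Stage names are hashed with CRC-32 so each pipeline stage draws an
    independent, reproducible stream; the result stays below 2**31.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % MAX_SEED


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
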