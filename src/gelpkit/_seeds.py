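"""Deterministic per-stage seed derivation.

A single master seed drives the whole pipeline; each stage derives its own
child seed by hashing the stage name, so stages can be re-run independently
and reproducibly without sharing RNG state.
"""

from __future__ import annotations

import zlib

__all__ = ["child_seed"]


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific seed from the master seed.

    The result is stable across runs and platforms and always fits in a
    non-negative 31-bit integer, safe for any RNG constructor.
    """
    h = zlib.crc32(f"{int(master_seed)}:{stage}".encode("utf-8"))
    return h & 0x7FFFFFFF
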