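"""Deterministic seed derivation.

All randomness in a run (LHS designs, GP restarts, differential evolution,
synthetic noise, bootstraps) flows from one master seed.  Child seeds are
derived by hashing the master seed together with a tuple of string/int tags,
so the same (master, tags) pair always yields the same child stream and
distinct tags yield independent streams.
"""

from __future__ import annotations

import zlib

__all__ = ["derive_seed"]

_MOD = 2**31 - 1


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from ``master`` and a tag sequence."""
    payload = repr((int(master),) + tuple(str(t) for t in tags)).encode()
    return zlib.crc32(payload) % _MOD
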