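"""Small shared helpers: seed derivation and config hashing."""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *parts) -> int:
    """Deterministically derive a sub-seed below 2**31 from a master seed
    and a stage label (stable across processes and platforms)."""
    h = hashlib.sha256(repr((int(master),) + parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def stable_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]
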