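"""Deterministic seed derivation.

Every source of randomness in the package receives a seed derived from a
single master seed plus a string tag, so the whole repeated-split protocol is
reproducible from one integer. Derivation is a SHA-256 hash of
``"<master>/<tag1>/<tag2>/..."`` reduced mod 2**31 — stable across platforms
and Python processes (unlike ``hash()``).
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tags: object) -> int:
    """Derive a child seed below 2**31 from a master seed and tags."""
    key = "/".join([str(int(master_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
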