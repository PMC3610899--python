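"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(*parts) -> int:
    """Deterministic sub-seed from heterogeneous parts, in [0, 2^31).

    Hash-based so per-subject / per-iteration streams are reproducible and
    independent of the order in which subjects are processed.
    """
    key = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)
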