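"""Shared helpers: seed derivation and logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("cnattention")


def derive_seed(seed: int, *tags: object) -> int:
    """Derive a stage-specific seed from a global seed and string/int tags.

    Decouples the random streams of pipeline stages: changing one stage's
    consumption of randomness does not perturb the others. Always < 2**31.
    """
    key = ":".join([str(int(seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
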