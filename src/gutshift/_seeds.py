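"""Stable sub-seed derivation.

Each stochastic pipeline stage consumes a sub-seed derived by hashing
(master_seed, stage_name), so adding or reordering stages never perturbs the
randomness of the others, and results are reproducible across platforms and
Python hash-randomization settings.
"""

import hashlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Return a deterministic 31-bit sub-seed for a named stage."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
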