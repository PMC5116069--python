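"""Shared helpers: seeding, output headers, logging setup."""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np

logger = logging.getLogger("paleoscan")

# msprime wants seeds in [1, 2^32); user-facing seeds stay below 2^31.
_MAX_SEED = 2**31 - 1


def rng_from_seed(seed) -> np.random.Generator:
    """Build a Generator from an int seed, a SeedSequence, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds from a master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % _MAX_SEED) + 1 for s in ss.spawn(n)]


def msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, _MAX_SEED))


def params_digest(params: dict) -> str:
    """Short stable digest of a parameter dictionary, for output headers."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(seed, params: dict | None = None) -> list[str]:
    from paleoscan import __version__

    lines = [f"# paleoscan {__version__}", f"# seed={seed}"]
    if params:
        lines.append(f"# params_digest={params_digest(params)}")
    return lines
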