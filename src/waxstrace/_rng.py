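"""Named, independent random substreams derived from one root seed.

Every stochastic operation in the package draws from a generator obtained
here, so adding a stage never shifts another stage's draws.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _name_key(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode("utf-8")).digest()[:4], "big")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names`` under ``seed``."""
    entropy = [int(seed)] + [_name_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, *names: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    return int(substream(seed, *names).integers(2**31))
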