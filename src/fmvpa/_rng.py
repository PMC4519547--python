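"""Named random substreams derived from a single master seed.

Every stochastic component of the pipeline (trial ordering, memory labels,
activation patterns, scanner noise, counterbalancing, permutations) draws
from its own named stream so that changing one component's consumption of
random numbers never perturbs another.
"""

import hashlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator seeded by (master_seed, name).

    The name is hashed with BLAKE2s so streams are stable across sessions
    and independent of each other for distinct names.
    """
    digest = hashlib.blake2s(name.encode("utf-8"), digest_size=8).digest()
    entropy = [int(master_seed) % (2**31), int.from_bytes(digest, "little")]
    return np.random.default_rng(entropy)
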