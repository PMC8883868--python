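"""Deterministic seed derivation.

A master seed plus an ordered tuple of small integer keys (stage code,
subject index, permutation index, ...) maps to an independent
``numpy.random.Generator``.  Because the child stream depends only on the
key tuple and not on how many other streams were created, adding subjects
or stages never perturbs existing ones.
"""

from __future__ import annotations

import numpy as np

# fixed stage codes used across the package
STAGE_SESSION = 1
STAGE_BEHAVIOR = 2
STAGE_DECODE_FOLDS = 3
STAGE_DECODE_PERM = 4
STAGE_CLUSTER = 5
STAGE_EEG = 6


def child_rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Generator for the stream identified by ``(master_seed, *keys)``."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, keys)]))


def child_int(master_seed: int, *keys: int) -> int:
    """A 31-bit integer seed derived from the same scheme (for sklearn)."""
    return int(child_rng(master_seed, *keys).integers(0, 2**31 - 1))
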