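"""Deterministic seed fan-out.

A single integer seed drives every stage. Each stage (and, where
appropriate, each subject) gets its own :class:`numpy.random.SeedSequence`
built from ``(global_seed, stage_id[, index])`` so that re-ordering or
parallelising subject-level work cannot change any draw.

The embedding stage deliberately uses one *shared* stage seed for all
subjects: identical graphs must produce identical walk corpora and
embeddings so that subject feature vectors are comparable coordinates in a
common space.
"""

from __future__ import annotations

import numpy as np

STAGE_SIMULATE = 11
STAGE_WALKS = 23
STAGE_SKIPGRAM = 37
STAGE_CV = 53
STAGE_CLASSIFIER = 67


def seed_sequence(global_seed: int, stage: int, index: int | None = None) -> np.random.SeedSequence:
    ent = [int(global_seed), int(stage)]
    if index is not None:
        ent.append(int(index))
    return np.random.SeedSequence(ent)


def rng_for(global_seed: int, stage: int, index: int | None = None) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(global_seed, stage, index))


def small_int_seed(global_seed: int, stage: int, index: int | None = None) -> int:
    """A sub-2^31 integer seed (for libraries that take plain ints)."""
    return int(seed_sequence(global_seed, stage, index).generate_state(1, np.uint32)[0] % (2**31 - 1))
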