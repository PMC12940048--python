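"""Seed management.

One master seed governs every source of randomness in a run.  Each stage
draws from its own labelled substream so that, e.g., changing the feature
selection budget cannot perturb the synthetic data or the train/test split.
"""

from __future__ import annotations

import numpy as np

# Fixed labels -> spawn keys.  Never reorder: the mapping is part of the
# reproducibility contract.
_STREAMS = {
    "synth": 0,
    "split": 1,
    "folds": 2,
    "bpo": 3,
    "dho": 4,
    "lstm": 5,
    "tune": 6,
    "fs_fitness": 7,
    "refit": 8,
    "baselines": 9,
}


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Return the labelled child generator of ``master_seed``."""
    if label not in _STREAMS:
        raise KeyError(f"unknown RNG stream label: {label!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STREAMS[label],))
    return np.random.default_rng(ss)


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
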