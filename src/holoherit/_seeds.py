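"""Counter-based derivation of per-stage child seeds from one run seed.

Each pipeline stage (genotypes, taxa, phenotypes, permutations, ...) gets its
own `numpy` Generator spawned from ``SeedSequence(seed, spawn_key=(stage,))``
so a stage can be regenerated in isolation and independent stages never share
a stream.
"""

from __future__ import annotations

import numpy as np

# stable stage indices; appending is fine, reordering is not
STAGES = {
    "genotypes": 0,
    "taxa": 1,
    "phenotypes": 2,
    "mantel": 3,
    "gwas": 4,
    "misc": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the deterministic Generator for one named pipeline stage."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGES)}")
    ss = np.random.SeedSequence(seed, spawn_key=(STAGES[stage],))
    return np.random.default_rng(ss)


def stage_seed(seed: int, stage: str) -> int:
    """A 31-bit integer child seed for APIs that want a plain int."""
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))
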