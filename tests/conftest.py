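import random

import pytest

from mitodiff.simulate import (DEFAULT_EVENT_COUNTS, SimConfig, compact_config,
                               simulate_genomes)

# most integration tests run on the compact study profile: the full event
# inventory on smaller sequences, so the search-backed stages stay fast
small_config = compact_config


def quiet_config(seed: int, **overrides) -> SimConfig:
    """No structural events: substitutions/indels only."""
    kw = dict(event_counts={k: 0 for k in DEFAULT_EVENT_COUNTS}, rotate=False)
    kw.update(overrides)
    return small_config(seed, **kw)


def evolve_codon_pairs(seed: int, omega: float, n: int = 10000,
                       rounds: int = 3, p: float = 0.3):
    """Codon pairs evolved under a known nonsynonymous/synonymous rate
    ratio: random single-base proposals, synonymous changes always
    accepted, nonsynonymous ones with probability omega, stops rejected."""
    import numpy as np

    from mitodiff.divergence import _aa

    rng = np.random.default_rng(seed)
    bases = "ACGT"
    pairs = []
    while len(pairs) < n:
        c = "".join(rng.choice(list(bases), 3))
        if _aa(c) == "*":
            continue
        m = c
        for _ in range(rounds):
            if rng.random() > p:
                continue
            k = int(rng.integers(0, 3))
            b = bases[int(rng.integers(0, 4))]
            if b == m[k]:
                continue
            cand = m[:k] + b + m[k + 1:]
            if _aa(cand) == "*":
                continue
            if _aa(cand) == _aa(m) or rng.random() < omega:
                m = cand
        pairs.append((c, m))
    return pairs


def random_seq(seed: int, n: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def trio():
    """One simulated trio with the full event inventory, shared read-only."""
    return simulate_genomes(small_config(1))


@pytest.fixture(scope="session")
def trio_default():
    """Default-scale trio (larger genomes) for the coarser checks."""
    return simulate_genomes(SimConfig(seed=1))
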