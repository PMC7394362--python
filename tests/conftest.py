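from __future__ import annotations

import numpy as np
import pytest

from bismine.roster import AMINO_ACIDS, default_roster
from bismine.synthetic import CohortSpec, generate_anchor_hits, generate_cohort, generate_genome


@pytest.fixture(scope="session")
def roster():
    return default_roster()


def make_batch(architecture: str, n: int, flank: int = 25, anchor_seed: int = 0):
    """n synthetic genomes of one architecture label plus their anchor tables."""
    genomes, anchors = [], {}
    for s in range(n):
        g = generate_genome(architecture, flank, seed=s)
        genomes.append(g)
        anchors[g.replicon_id] = generate_anchor_hits(g, seed=anchor_seed)
    return genomes, anchors


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort with donor structure: 20 healthy, 10+10 IBD, 5 prediabetes."""
    spec = CohortSpec(
        n_donors_per_group={"healthy": 20, "ibd_cd": 10, "ibd_uc": 10, "prediabetes": 5},
        seed=11,
    )
    profiles, donors = generate_cohort(spec)
    return spec, profiles, donors


@pytest.fixture(scope="session")
def shifted_cohort():
    """Cohort with a planted healthy-vs-IBD carriage shift of 2."""
    spec = CohortSpec(
        n_donors_per_group={"healthy": 100, "ibd_cd": 50, "ibd_uc": 50, "prediabetes": 28},
        median_shift=2.0,
        seed=5,
    )
    profiles, donors = generate_cohort(spec)
    return spec, profiles, donors


def random_seqs(rng: np.random.Generator, n: int, min_len: int = 1, max_len: int = 8):
    alphabet = list(AMINO_ACIDS)
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(alphabet, size=length)))
    return out
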