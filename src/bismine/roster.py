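"""The 18-protein BIS roster.

The *Bacteroidales* injection system (BIS) is a phage-tail-like contractile
apparatus encoded by a conserved gene cluster.  Screening of metagenomes and
metatranscriptomes is carried out against a fixed roster of 18 proteins:
two sheaths, two tubes, the three baseplate components (gp25, gp27, gp6), an
FtsH-like ATPase, LysM, Spike, Tip, the DUF4255 and DUF4157 domain proteins,
and five hypothetical proteins.

Reference amino-acid sequences for the roster are generated deterministically
(synthetic stand-ins for the real cluster proteins; see :mod:`bismine.synthetic`)
so that role annotation and clustering behave reproducibly without any
external database.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: allowed functional role labels
ROLES = (
    "sheath",
    "tube",
    "baseplate_gp25",
    "baseplate_gp27",
    "baseplate_gp6",
    "ftsh_atpase",
    "lysm",
    "spike",
    "tip",
    "duf4255",
    "duf4157",
    "hypothetical",
)

# name -> (role, length in amino acids).  Lengths sit in a narrow band
# (130-185 aa): percent identity over the shorter sequence saturates for
# unrelated sequences once lengths differ by more than ~1.6x, so keeping
# the generated proteins comparable in size keeps the 50% clustering
# threshold discriminative.
_ROSTER_TABLE = {
    "Sheath1": ("sheath", 178),
    "Sheath2": ("sheath", 170),
    "Tube1": ("tube", 140),
    "Tube2": ("tube", 145),
    "FtsH/ATPase": ("ftsh_atpase", 185),
    "gp25": ("baseplate_gp25", 138),
    "gp27": ("baseplate_gp27", 160),
    "gp6": ("baseplate_gp6", 155),
    "LysM": ("lysm", 136),
    "Spike": ("spike", 165),
    "Tip": ("tip", 148),
    "DUF4255": ("duf4255", 152),
    "DUF4157": ("duf4157", 142),
    "Hyp1": ("hypothetical", 134),
    "Hyp2": ("hypothetical", 131),
    "Hyp3": ("hypothetical", 130),
    "Hyp4": ("hypothetical", 137),
    "Hyp5": ("hypothetical", 133),
}

#: the ten genes that cooccur at high frequency in gut metagenomes
CORE_TEN = (
    "Sheath1",
    "Sheath2",
    "FtsH/ATPase",
    "gp25",
    "gp27",
    "gp6",
    "LysM",
    "Spike",
    "Hyp1",
    "Hyp2",
)

# internal seed for the deterministic reference sequences
_REFERENCE_SEED = 1729


@dataclass(frozen=True)
class GeneSpec:
    """One roster gene: its label, functional role and length."""

    name: str
    role: str
    length_aa: int

    @property
    def length_nt(self) -> int:
        """Nucleotide length of the coding gene (includes the stop codon)."""
        return 3 * self.length_aa + 3


@dataclass(frozen=True)
class BisRoster:
    """Ordered collection of the 18 BIS gene descriptors.

    ``reference_sequences`` maps gene name to a reference amino-acid
    sequence used for role annotation of cluster representatives.
    """

    genes: tuple[GeneSpec, ...]
    reference_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(names) != 18:
            raise ValueError(f"roster must contain exactly 18 genes, got {len(names)}")
        if len(set(names)) != 18:
            raise ValueError("roster gene names must be unique")
        for g in self.genes:
            if g.role not in ROLES:
                raise ValueError(f"unknown role {g.role!r} for gene {g.name!r}")
            if g.length_aa <= 0:
                raise ValueError(f"gene {g.name!r} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, name: str) -> GeneSpec:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def role_of(self, name: str) -> str:
        return self[name].role

    def length_nt(self, name: str) -> int:
        return self[name].length_nt


def random_protein(length: int, rng: np.random.Generator) -> str:
    """A uniformly random amino-acid sequence of the given length."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@functools.lru_cache(maxsize=1)
def default_roster() -> BisRoster:
    """The default 18-gene roster with deterministic reference sequences."""
    genes = tuple(
        GeneSpec(name, role, length) for name, (role, length) in _ROSTER_TABLE.items()
    )
    refs: dict[str, str] = {}
    for k, g in enumerate(genes):
        rng = np.random.default_rng([_REFERENCE_SEED, k])
        refs[g.name] = random_protein(g.length_aa, rng)
    return BisRoster(genes=genes, reference_sequences=refs)
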