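"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here, so all stages are
testable without any external download:

* genomes with a planted BIS locus in one of the three conserved
  architectures (plus negative controls and a lone-sheath decoy),
* fecal-metagenome cohorts with donor structure, negative-binomial per-gene
  hit counts and a planted healthy-vs-IBD shift in donor gene carriage,
* per-read tabular alignment records (12-column BLAST-style layout) whose
  true hits sit below the E = 0.001 screening cutoff and whose decoys sit
  above it,
* MetaPhlAn-style clade/relative-abundance taxonomic profiles with a
  phylum-level Bacteroidetes row.

Planted locus proteins are mutated copies (<= ~20% substituted positions) of
the deterministic roster reference sequences, so within-role identity stays
above the 50% clustering threshold and between-role identity below it.
Flanking proteins are mutated copies drawn from a fixed pool of decoy
families, emulating the paralogous gene families of real genomes; decoy
families form their own clusters but receive no roster annotation.
"""

from __future__ import annotations

import functools
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roster import AMINO_ACIDS, CORE_TEN, BisRoster, default_roster, random_protein
from .types import (
    GROUPS,
    IBD_GROUPS,
    AnchorHit,
    GenomeProteinTable,
    Protein,
    SampleHitProfile,
)

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

#: gene order of the three conserved architectures.  Architecture 1 carries
#: two sheath and two tube genes with hypothetical proteins between Tube2 and
#: LysM and between gp25 and gp27; architecture 2 drops those hypotheticals
#: and the second sheath; architecture 3 is the compact form, lacking four
#: hypotheticals, with shortened gp27/gp6 and the FtsH/ATPase-DUF4157 pair
#: inverted (realized here as the locus in opposite orientation, so
#: FtsH/ATPase precedes DUF4157 in genome order).
ARCHITECTURE_TEMPLATES: dict[str, tuple[str, ...]] = {
    "1": (
        "DUF4255", "Hyp1", "Sheath1", "Sheath2", "Tube1", "Tube2", "Hyp2",
        "LysM", "Spike", "Tip", "gp25", "Hyp3", "gp27", "gp6", "Hyp4",
        "Hyp5", "DUF4157", "FtsH/ATPase",
    ),
    "2": (
        "DUF4255", "Hyp1", "Sheath1", "Tube1", "Tube2", "LysM", "Spike",
        "Tip", "gp25", "gp27", "gp6", "Hyp4", "Hyp5", "DUF4157", "FtsH/ATPase",
    ),
    "3": (
        "FtsH/ATPase", "DUF4157", "Hyp5", "gp6", "gp27", "gp25", "Tip",
        "Spike", "LysM", "Tube2", "Tube1", "Sheath1", "DUF4255",
    ),
}

GENOME_KINDS = tuple(ARCHITECTURE_TEMPLATES) + ("none", "decoy")

_DECOY_POOL_SEED = 424243
_N_DECOY_FAMILIES = 30

_SHEATH_PROFILE = "phage_sheath_1"


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


def _mutate(sequence: str, rng: np.random.Generator, max_rate: float = 0.18) -> str:
    """Substitute a random <= ``max_rate`` fraction of positions."""
    rate = rng.uniform(0.05, max_rate)
    n_mut = int(round(rate * len(sequence)))
    if n_mut == 0:
        return sequence
    positions = rng.choice(len(sequence), size=n_mut, replace=False)
    chars = list(sequence)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


@functools.lru_cache(maxsize=1)
def _decoy_pool() -> tuple[str, ...]:
    """Fixed ancestor sequences for the non-BIS flanking gene families."""
    rng = np.random.default_rng(_DECOY_POOL_SEED)
    lengths = rng.integers(130, 186, size=_N_DECOY_FAMILIES)
    return tuple(random_protein(int(n), rng) for n in lengths)


def generate_genome(
    architecture: str,
    flank_genes: int = 25,
    seed: int = 0,
    roster: BisRoster | None = None,
) -> GenomeProteinTable:
    """One replicon protein table with an optional planted BIS locus.

    ``architecture`` is one of ``"1"``, ``"2"``, ``"3"`` (planted locus in
    that arrangement), ``"none"`` (random proteins only) or ``"decoy"``
    (a lone sheath-like gene with no accompanying cluster).  ``flank_genes``
    random-family proteins are placed on each side of the planted locus.
    Deterministic for a fixed seed; the planted ground truth is stored in
    ``table.attrs["planted"]`` (protein_id -> roster gene name).
    """
    architecture = str(architecture)
    if architecture not in GENOME_KINDS:
        raise ValueError(
            f"unknown architecture {architecture!r}; expected one of {GENOME_KINDS}"
        )
    if flank_genes < 0:
        raise ValueError("flank_genes must be >= 0")
    if roster is None:
        roster = default_roster()
    rng = np.random.default_rng([seed, _crc(architecture)])
    pool = _decoy_pool()

    def flank_block(n: int) -> list[tuple[str | None, str]]:
        block = []
        for _ in range(n):
            ancestor = pool[rng.integers(len(pool))]
            block.append((None, _mutate(ancestor, rng)))
        return block

    # (gene_name or None, sequence) in genome order
    genes: list[tuple[str | None, str]] = list(flank_block(flank_genes))
    if architecture in ARCHITECTURE_TEMPLATES:
        for name in ARCHITECTURE_TEMPLATES[architecture]:
            ancestor = roster.reference_sequences[name]
            if architecture == "3" and name in ("gp27", "gp6"):
                # the compact architecture carries shortened gp27/gp6
                ancestor = ancestor[: int(0.85 * len(ancestor))]
            genes.append((name, _mutate(ancestor, rng)))
    elif architecture == "decoy":
        genes.append(("SheathLike", _mutate(roster.reference_sequences["Sheath1"], rng)))
    genes.extend(flank_block(flank_genes))

    locus_strand = "-" if architecture == "3" else "+"
    replicon_id = f"synth_{architecture}_s{seed}"
    proteins: list[Protein] = []
    planted: dict[str, str] = {}
    pos = 1
    for idx, (name, seq) in enumerate(genes):
        pid = f"{replicon_id}_p{idx:04d}"
        nt = 3 * len(seq) + 3
        strand = locus_strand if name is not None else ("+", "-")[rng.integers(2)]
        proteins.append(
            Protein(
                protein_id=pid,
                start=pos,
                end=pos + nt - 1,
                strand=strand,
                sequence=seq,
                index=idx,
            )
        )
        if name is not None:
            planted[pid] = name
        pos += nt + int(rng.integers(20, 200))

    return GenomeProteinTable(
        replicon_id=replicon_id,
        proteins=proteins,
        attrs={"planted": planted, "architecture": architecture, "seed": seed},
    )


def generate_anchor_hits(genome: GenomeProteinTable, seed: int = 0) -> list[AnchorHit]:
    """Sheath-profile hit records for a synthetic genome.

    Planted sheath genes (and the decoy's lone sheath-like gene) receive
    hits comfortably above the gathering threshold; two spurious hits are
    added below it (one failing the bit score, one failing the E-value) to
    exercise anchor filtering.
    """
    rng = np.random.default_rng([seed, _crc(genome.replicon_id)])
    planted: dict[str, str] = genome.attrs.get("planted", {})
    sheath_ids = [
        pid for pid, g in planted.items() if g in ("Sheath1", "Sheath2", "SheathLike")
    ]
    hits = [
        AnchorHit(
            protein_id=pid,
            bitscore=round(float(rng.uniform(80, 400)), 1),
            evalue=float(10.0 ** rng.uniform(-60, -15)),
            profile_name=_SHEATH_PROFILE,
        )
        for pid in sheath_ids
    ]
    others = [p.protein_id for p in genome if p.protein_id not in planted]
    if len(others) >= 2:
        weak = [others[int(k)] for k in rng.choice(len(others), size=2, replace=False)]
        hits.append(
            AnchorHit(weak[0], round(float(rng.uniform(5, 31)), 1), 1e-20, _SHEATH_PROFILE)
        )
        hits.append(
            AnchorHit(
                weak[1],
                round(float(rng.uniform(50, 200)), 1),
                float(10.0 ** rng.uniform(-8, -1)),
                _SHEATH_PROFILE,
            )
        )
    return hits


@dataclass
class GroupCountModel:
    """Negative-binomial per-gene count model for one donor group."""

    gene_means: dict[str, float]
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if any(m < 0 for m in self.gene_means.values()):
            raise ValueError("gene means must be non-negative")


def default_count_model(roster: BisRoster | None = None) -> GroupCountModel:
    """Core-ten genes at higher mean depth than the peripheral eight."""
    if roster is None:
        roster = default_roster()
    means = {g.name: (3.0 if g.name in CORE_TEN else 1.2) for g in roster}
    return GroupCountModel(gene_means=means)


@dataclass
class CohortSpec:
    """Study design for a synthetic fecal-metagenome cohort.

    The planted healthy-vs-IBD effect acts on donor gene *carriage*: each
    donor carries a random subset of the 18 roster genes whose size is drawn
    around ``presence_mean`` (lowered by ``median_shift`` for the IBD
    subgroups), and carried genes are guaranteed at least one read hit in at
    least one of the donor's samples.  Per-sample counts of carried genes
    follow the group's negative-binomial model.
    """

    n_donors_per_group: dict[str, int]
    samples_per_donor: tuple[int, int] = (1, 3)
    group_count_model: dict[str, GroupCountModel] = field(default_factory=dict)
    median_shift: float = 0.0
    presence_mean: float = 12.0
    presence_sd: float = 2.5
    total_reads_model: tuple[float, float] = (math.log(2e6), 0.5)
    bacteroidetes_model: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_donors_per_group:
            raise ValueError("at least one donor group is required")
        unknown = set(self.n_donors_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}; allowed: {GROUPS}")
        if any(n < 1 for n in self.n_donors_per_group.values()):
            raise ValueError("each group needs >= 1 donor")
        lo, hi = self.samples_per_donor
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_donor must be a range with 1 <= lo <= hi")
        for g in self.n_donors_per_group:
            self.group_count_model.setdefault(g, default_count_model())
            self.bacteroidetes_model.setdefault(g, (8.0, 6.0))


@dataclass
class DonorRecord:
    """Ground-truth record for one generated donor."""

    donor_id: str
    group: str
    carried: tuple[str, ...]
    presence_count: int
    sample_ids: list[str]
    bacteroidetes_by_sample: dict[str, float]

    @property
    def bacteroidetes_abundance(self) -> float:
        return float(np.mean(list(self.bacteroidetes_by_sample.values())))


def generate_cohort(
    spec: CohortSpec, roster: BisRoster | None = None
) -> tuple[list[SampleHitProfile], list[DonorRecord]]:
    """Simulate per-sample roster hit counts with donor structure."""
    if roster is None:
        roster = default_roster()
    rng = np.random.default_rng(spec.seed)
    gene_names = roster.names
    weights = np.array([3.0 if g in CORE_TEN else 1.0 for g in gene_names])
    weights = weights / weights.sum()
    mu_log, sigma_log = spec.total_reads_model

    profiles: list[SampleHitProfile] = []
    donors: list[DonorRecord] = []
    for group in sorted(spec.n_donors_per_group):
        model = spec.group_count_model[group]
        beta_a, beta_b = spec.bacteroidetes_model[group]
        shift = spec.median_shift if group in IBD_GROUPS else 0.0
        for d in range(spec.n_donors_per_group[group]):
            donor_id = f"{group}_d{d:03d}"
            k_carried = int(np.clip(round(rng.normal(spec.presence_mean - shift, spec.presence_sd)), 0, 18))
            carried_idx = rng.choice(18, size=k_carried, replace=False, p=weights)
            carried = tuple(gene_names[i] for i in sorted(carried_idx))
            n_samples = int(rng.integers(spec.samples_per_donor[0], spec.samples_per_donor[1] + 1))

            sample_counts: list[dict[str, int]] = []
            sample_ids: list[str] = []
            bact: dict[str, float] = {}
            for s in range(n_samples):
                sample_id = f"{donor_id}_s{s}"
                counts = {g: 0 for g in gene_names}
                for g in carried:
                    mean = model.gene_means.get(g, 1.0)
                    p = model.dispersion / (model.dispersion + mean)
                    counts[g] = int(rng.negative_binomial(model.dispersion, p))
                sample_counts.append(counts)
                sample_ids.append(sample_id)
                bact[sample_id] = round(100.0 * float(rng.beta(beta_a, beta_b)), 5)
            # carriage guarantee: every carried gene detected in >= 1 sample
            for g in carried:
                if all(c[g] == 0 for c in sample_counts):
                    sample_counts[int(rng.integers(n_samples))][g] = 1

            for sample_id, counts in zip(sample_ids, sample_counts):
                total_reads = max(1, int(round(rng.lognormal(mu_log, sigma_log))))
                profiles.append(
                    SampleHitProfile(
                        sample_id=sample_id,
                        donor_id=donor_id,
                        body_site="gut",
                        total_reads=total_reads,
                        counts=counts,
                    )
                )
            donors.append(
                DonorRecord(
                    donor_id=donor_id,
                    group=group,
                    carried=carried,
                    presence_count=k_carried,
                    sample_ids=sample_ids,
                    bacteroidetes_by_sample=bact,
                )
            )
    return profiles, donors


def generate_alignment_hits(
    profile: SampleHitProfile,
    roster: BisRoster | None = None,
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-read alignment records (12-column BLAST-style) for one sample.

    Exactly the profile's counts pass the E <= 0.001 screening cutoff (true
    hits drawn log-uniform in [1e-30, 1e-3]); an additional ``decoy_rate``
    fraction of records carries E in (0.001, 10] and must be removed by the
    downstream filter.  Byte-identical for a fixed seed.
    """
    if not (0 <= decoy_rate <= 1):
        raise ValueError("decoy_rate must be in [0, 1]")
    if roster is None:
        roster = default_roster()
    rng = np.random.default_rng([seed, _crc(profile.sample_id)])
    rows: list[list] = []
    read_no = 0

    def make_row(gene: str, evalue: float) -> list:
        nonlocal read_no
        gene_len = roster[gene].length_aa
        pident = round(float(rng.uniform(60, 100)), 1)
        aln_len = int(rng.integers(20, 34))
        sstart = int(rng.integers(1, max(2, gene_len - aln_len + 1)))
        row = [
            f"{profile.sample_id}_r{read_no:06d}",
            gene,
            pident,
            aln_len,
            int(round(aln_len * (1 - pident / 100))),
            0,
            1,
            3 * aln_len,
            sstart,
            sstart + aln_len - 1,
            float(evalue),
            round(float(rng.uniform(40, 200)), 1),
        ]
        read_no += 1
        return row

    n_true = 0
    for gene in roster.names:
        c = int(profile.counts.get(gene, 0))
        n_true += c
        for _ in range(c):
            rows.append(make_row(gene, 10.0 ** rng.uniform(-30, -3)))
    n_decoy = int(round(decoy_rate * n_true))
    for _ in range(n_decoy):
        gene = roster.names[int(rng.integers(18))]
        rows.append(make_row(gene, 10.0 ** rng.uniform(-2.9, 1.0)))
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


_OTHER_PHYLA = ("Firmicutes", "Proteobacteria", "Actinobacteria", "Verrucomicrobia")


def generate_taxonomic_profiles(
    donors: list[DonorRecord], spec: CohortSpec
) -> dict[str, pd.DataFrame]:
    """MetaPhlAn-style clade/abundance tables, one per sample.

    Each table has a kingdom row (100.0) and phylum rows that sum to 100,
    including the donor's planted per-sample Bacteroidetes abundance.
    """
    if not donors:
        raise ValueError("cohort must be nonempty")
    out: dict[str, pd.DataFrame] = {}
    for donor in donors:
        for sample_id in donor.sample_ids:
            rng = np.random.default_rng([spec.seed, 7, _crc(sample_id)])
            b = donor.bacteroidetes_by_sample[sample_id]
            rest = 100.0 - b
            split = rng.dirichlet(np.ones(len(_OTHER_PHYLA))) * rest
            vals = [round(float(v), 5) for v in split[:-1]]
            vals.append(round(rest - sum(vals), 5))
            rows = [("k__Bacteria", 100.0), ("k__Bacteria|p__Bacteroidetes", b)]
            rows += [
                (f"k__Bacteria|p__{name}", v) for name, v in zip(_OTHER_PHYLA, vals)
            ]
            out[sample_id] = pd.DataFrame(rows, columns=["clade", "abundance"])
    return out
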