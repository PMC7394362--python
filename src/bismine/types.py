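"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

BODY_SITES = ("gut", "oral", "nasal", "vaginal", "skin", "other")
GROUPS = ("healthy", "ibd_cd", "ibd_uc", "prediabetes")
IBD_GROUPS = ("ibd_cd", "ibd_uc")
ARCHITECTURES = ("1", "2", "3", "unclassified")


@dataclass(frozen=True)
class Protein:
    """One protein-coding gene of a replicon, in genome order."""

    protein_id: str
    start: int  # 1-based nucleotide coordinate
    end: int
    strand: str  # '+' or '-'
    sequence: str
    index: int  # 0-based rank in genome order

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.protein_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein_id}: bad strand {self.strand!r}")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")


@dataclass
class GenomeProteinTable:
    """Ordered proteins of one replicon with coordinates and sequences.

    ``attrs`` carries optional free-form metadata (e.g. the synthetic
    generator stores its planted ground truth there).
    """

    replicon_id: str
    proteins: list[Protein]
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, p in enumerate(self.proteins):
            if p.index != k:
                raise ValueError(
                    f"protein indices must be consecutive from 0; "
                    f"{p.protein_id} has index {p.index} at rank {k}"
                )
        starts = [p.start for p in self.proteins]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("start coordinates must be non-decreasing in index order")

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def get(self, protein_id: str) -> Protein:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(protein_id)

    def has(self, protein_id: str) -> bool:
        return any(p.protein_id == protein_id for p in self.proteins)


@dataclass(frozen=True)
class AnchorHit:
    """A profile-search hit of one protein against the sheath HMM."""

    protein_id: str
    bitscore: float
    evalue: float
    profile_name: str = "phage_sheath_1"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.protein_id}: negative E-value")


@dataclass
class ProteinCluster:
    """A greedy identity cluster; the centroid is always a member."""

    centroid_id: str
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its own cluster")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class GeneCall:
    protein_id: str
    role: str  # roster role or "unannotated"


@dataclass
class BisLocus:
    """A trimmed candidate BIS gene cluster with role calls."""

    replicon_id: str
    gene_calls: list[GeneCall]
    architecture: str = "unclassified"
    complete: bool = False

    def __post_init__(self) -> None:
        if not self.gene_calls:
            raise ValueError("locus must contain at least one gene call")
        if not self.complete and self.architecture != "unclassified":
            raise ValueError("incomplete loci must be unclassified")

    @property
    def roles(self) -> list[str]:
        return [c.role for c in self.gene_calls]

    def role_count(self, role: str) -> int:
        return sum(1 for c in self.gene_calls if c.role == role)


@dataclass
class SampleHitProfile:
    """Per-sample hit counts against the 18-gene roster."""

    sample_id: str
    donor_id: str
    body_site: str
    total_reads: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.body_site not in BODY_SITES:
            raise ValueError(f"{self.sample_id}: unknown body site {self.body_site!r}")
        if self.total_reads < 1:
            raise ValueError(f"{self.sample_id}: total_reads must be >= 1")
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"{self.sample_id}: negative count for {g}")

    @property
    def has_any_hit(self) -> bool:
        return any(c > 0 for c in self.counts.values())


@dataclass
class DonorProfile:
    """Donor-level aggregate: per-gene mean hits and the presence count."""

    donor_id: str
    group: str
    n_samples: int
    mean_counts: dict[str, float]
    presence_count: int
    bacteroidetes_abundance: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.donor_id}: unknown group {self.group!r}")
        expected = sum(1 for v in self.mean_counts.values() if v > 0)
        if self.presence_count != expected:
            raise ValueError(
                f"{self.donor_id}: presence_count {self.presence_count} does not "
                f"match nonzero mean counts ({expected})"
            )


@dataclass
class ExpressionProfile:
    """Per-sample normalized expression of the roster genes."""

    sample_id: str
    total_reads: int
    raw_counts: dict[str, int]
    expression: dict[str, float]

    def __post_init__(self) -> None:
        for g, c in self.raw_counts.items():
            e = self.expression.get(g, 0.0)
            if (c == 0) != (e == 0.0):
                raise ValueError(f"{self.sample_id}: expression/count mismatch for {g}")


@dataclass
class BootstrapResult:
    """Percentile-bootstrap CI for a difference in group medians."""

    group_a: str
    group_b: str
    metric: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    alpha: float
    n_a: int
    n_b: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")

    @property
    def significant(self) -> bool:
        """True iff the CI does not cover zero."""
        return self.ci_low > 0 or self.ci_high < 0


def as_count_vector(counts: Mapping[str, int], gene_names: list[str]) -> list[int]:
    """Counts mapping -> dense vector in roster order (missing genes are 0)."""
    return [int(counts.get(g, 0)) for g in gene_names]
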