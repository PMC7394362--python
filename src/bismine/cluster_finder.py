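"""Genome-neighborhood mining for BIS gene clusters.

The search follows the anchor-and-expand strategy used for contractile
injection systems: proteins matching the phage sheath profile above the
gathering threshold (bit score > 31.4, E < 1e-9) seed a neighborhood of up to
20 proteins on either side; pooled neighborhood proteins are sorted by length
and greedily clustered at 50% amino-acid identity; clusters with >= 4 members
are kept and their representatives annotated against the 18-protein roster;
each neighborhood is then trimmed to the DUF4255 .. FtsH/ATPase span,
assessed for completeness (baseplate gp25/gp27/gp6, sheath, tube and the
FtsH/ATPase all present) and assigned one of the three conserved
architectures.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence

from .align import align_stats, pairwise_identity
from .roster import BisRoster, default_roster
from .types import AnchorHit, BisLocus, GeneCall, GenomeProteinTable, Protein, ProteinCluster

logger = logging.getLogger(__name__)

ANCHOR_MIN_BITSCORE = 31.4
ANCHOR_MAX_EVALUE = 1e-9
DEFAULT_FLANK = 20
IDENTITY_THRESHOLD = 0.5
MIN_CLUSTER_SIZE = 4
ANNOTATION_MIN_IDENTITY = 0.4
ANNOTATION_MIN_COVERAGE = 0.5
ANNOTATION_MIN_SCORE = 0

#: roles that must all be present for a locus to be called complete
CORE_ROLES = (
    "baseplate_gp25",
    "baseplate_gp27",
    "baseplate_gp6",
    "sheath",
    "tube",
    "ftsh_atpase",
)


def filter_anchor_hits(
    hits: Iterable[AnchorHit],
    min_bitscore: float = ANCHOR_MIN_BITSCORE,
    max_evalue: float = ANCHOR_MAX_EVALUE,
) -> list[AnchorHit]:
    """Keep hits above the sheath-profile gathering threshold.

    Both inequalities are strict (bit score > 31.4 AND E-value < 1e-9);
    input order is preserved.
    """
    return [h for h in hits if h.bitscore > min_bitscore and h.evalue < max_evalue]


def extract_neighborhood(
    genome: GenomeProteinTable, anchor_protein_id: str, flank: int = DEFAULT_FLANK
) -> list[Protein]:
    """Proteins within ``flank`` positions of the anchor, clipped to bounds."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    anchor_index = None
    for p in genome:
        if p.protein_id == anchor_protein_id:
            anchor_index = p.index
            break
    if anchor_index is None:
        raise KeyError(
            f"anchor protein {anchor_protein_id!r} not found in replicon "
            f"{genome.replicon_id!r}"
        )
    lo = max(0, anchor_index - flank)
    hi = min(len(genome) - 1, anchor_index + flank)
    return list(genome.proteins[lo : hi + 1])


def greedy_cluster(
    proteins: Sequence[tuple[str, str]], identity_threshold: float = IDENTITY_THRESHOLD
) -> list[ProteinCluster]:
    """UCLUST-style greedy centroid clustering.

    Proteins are processed in decreasing length order (ties broken by
    ascending id); each protein joins the earliest-founded centroid whose
    identity reaches the threshold, otherwise it founds a new cluster.
    The result partitions the input and is insensitive to input order.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity threshold must be in (0, 1]")
    ordered = sorted(proteins, key=lambda t: (-len(t[1]), t[0]))
    clusters: list[ProteinCluster] = []
    centroid_seqs: list[str] = []
    for pid, seq in ordered:
        placed = False
        for k, cseq in enumerate(centroid_seqs):
            if pairwise_identity(seq, cseq) >= identity_threshold:
                clusters[k].member_ids.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(ProteinCluster(centroid_id=pid, member_ids=[pid]))
            centroid_seqs.append(seq)
    return clusters


def filter_clusters(
    clusters: Iterable[ProteinCluster], min_size: int = MIN_CLUSTER_SIZE
) -> list[ProteinCluster]:
    """Keep clusters with >= ``min_size`` members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in clusters if c.size >= min_size]


def annotate_roles(
    representatives: Mapping[str, str],
    reference: BisRoster | None = None,
    min_identity: float = ANNOTATION_MIN_IDENTITY,
    min_coverage: float = ANNOTATION_MIN_COVERAGE,
    min_score: float = ANNOTATION_MIN_SCORE,
) -> dict[str, str]:
    """Assign a roster role to each cluster representative by best-hit alignment.

    A representative is annotated with the role of its best-scoring roster
    reference, provided the alignment score exceeds ``min_score`` and the
    alignment reaches ``min_identity`` identity over at least
    ``min_coverage`` of the shorter sequence; otherwise it is
    "unannotated".  All cluster members inherit their centroid's role.
    A strictly positive score requirement separates true roster homologs
    (strongly positive) from unrelated proteins (strongly negative under
    global alignment) far more sharply than identity alone.
    """
    if reference is None:
        reference = default_roster()
    missing = [g.name for g in reference if g.name not in reference.reference_sequences]
    if missing:
        raise ValueError(f"reference sequences missing for: {', '.join(missing)}")
    roles: dict[str, str] = {}
    for rep_id, rep_seq in representatives.items():
        best_score = None
        best_role = "unannotated"
        for gene in reference:
            ref_seq = reference.reference_sequences[gene.name]
            score, ident, aligned = align_stats(rep_seq, ref_seq)
            shorter = min(len(rep_seq), len(ref_seq))
            if score <= min_score:
                continue
            if ident / shorter < min_identity or aligned / shorter < min_coverage:
                continue
            if best_score is None or score > best_score:
                best_score = score
                best_role = gene.role
        roles[rep_id] = best_role
    return roles


def trim_locus(neighborhood_calls: Sequence[GeneCall], replicon_id: str) -> BisLocus:
    """Trim an annotated neighborhood to the conserved locus span.

    The span is bounded (inclusive) by the outermost calls of DUF4255 and
    FtsH/ATPase, the two boundary genes of the conserved cluster.  When
    either boundary role is missing the span runs from the first to the last
    annotated role.  A neighborhood with no annotated role at all is
    rejected.
    """
    boundary_idx = [
        k for k, c in enumerate(neighborhood_calls) if c.role in ("duf4255", "ftsh_atpase")
    ]
    annotated_idx = [
        k for k, c in enumerate(neighborhood_calls) if c.role != "unannotated"
    ]
    if not annotated_idx:
        raise ValueError(f"{replicon_id}: no annotated roles in neighborhood")
    if len({neighborhood_calls[k].role for k in boundary_idx}) == 2:
        lo, hi = min(boundary_idx), max(boundary_idx)
    else:
        lo, hi = min(annotated_idx), max(annotated_idx)
    return BisLocus(
        replicon_id=replicon_id, gene_calls=list(neighborhood_calls[lo : hi + 1])
    )


def assess_completeness(locus: BisLocus) -> bool:
    """True iff every core structural role is called at least once."""
    present = set(locus.roles)
    return all(r in present for r in CORE_ROLES)


def classify_architecture(locus: BisLocus) -> str:
    """Assign one of the three conserved gene arrangements.

    Architecture 3 is the compact form in which the FtsH/ATPase and DUF4157
    genes are inverted relative to architectures 1/2, so the FtsH/ATPase
    call precedes the DUF4157 call in locus order.  Otherwise, two sheath
    and two tube genes give architecture 1 and a single sheath gives
    architecture 2.  Incomplete loci are always unclassified.
    """
    if not assess_completeness(locus):
        return "unclassified"
    roles = locus.roles
    ftsh = next((k for k, r in enumerate(roles) if r == "ftsh_atpase"), None)
    duf4157 = next((k for k, r in enumerate(roles) if r == "duf4157"), None)
    if ftsh is not None and duf4157 is not None and ftsh < duf4157:
        return "3"
    n_sheath = locus.role_count("sheath")
    n_tube = locus.role_count("tube")
    if n_sheath >= 2 and n_tube >= 2:
        return "1"
    if n_sheath == 1:
        return "2"
    return "unclassified"


def _merge_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent [lo, hi] index ranges (inclusive)."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(ranges):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def find_loci(
    genomes: Iterable[GenomeProteinTable],
    anchor_hits: Mapping[str, Iterable[AnchorHit]],
    reference: BisRoster | None = None,
    flank: int = DEFAULT_FLANK,
    identity_threshold: float = IDENTITY_THRESHOLD,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    min_bitscore: float = ANCHOR_MIN_BITSCORE,
    max_evalue: float = ANCHOR_MAX_EVALUE,
) -> list[BisLocus]:
    """End-to-end locus discovery over a set of genomes.

    ``anchor_hits`` maps replicon_id to its sheath-profile hit records.
    Neighborhood proteins are pooled across all genomes before clustering
    (role annotation needs cluster sizes to clear the >= 4-member filter,
    so this routine is meant to be run on a batch of genomes, mirroring a
    multi-genome survey).  Neighborhoods from multiple anchors on one
    replicon are merged before trimming so one physical locus is reported
    once.
    """
    genomes = list(genomes)
    neighborhoods: list[tuple[GenomeProteinTable, tuple[int, int]]] = []
    pooled: dict[tuple[str, str], str] = {}

    for genome in genomes:
        hits = filter_anchor_hits(
            anchor_hits.get(genome.replicon_id, []), min_bitscore, max_evalue
        )
        ranges = []
        for h in hits:
            if not genome.has(h.protein_id):
                logger.warning(
                    "%s: anchor hit %s not in protein table; skipped",
                    genome.replicon_id,
                    h.protein_id,
                )
                continue
            nb = extract_neighborhood(genome, h.protein_id, flank)
            ranges.append((nb[0].index, nb[-1].index))
        for lo, hi in _merge_ranges(ranges):
            neighborhoods.append((genome, (lo, hi)))
            for p in genome.proteins[lo : hi + 1]:
                pooled[(genome.replicon_id, p.protein_id)] = p.sequence

    if not neighborhoods:
        return []

    # cluster pooled proteins; keys are "replicon::protein" to stay unique
    flat = [(f"{rep}::{pid}", seq) for (rep, pid), seq in sorted(pooled.items())]
    clusters = greedy_cluster(flat, identity_threshold)
    kept = filter_clusters(clusters, min_cluster_size)
    logger.info(
        "clustered %d neighborhood proteins into %d clusters (%d with >=%d members)",
        len(flat),
        len(clusters),
        len(kept),
        min_cluster_size,
    )

    seqs = dict(flat)
    rep_seqs = {c.centroid_id: seqs[c.centroid_id] for c in kept}
    rep_roles = annotate_roles(rep_seqs, reference)
    member_role: dict[str, str] = {}
    for c in kept:
        role = rep_roles[c.centroid_id]
        for m in c.member_ids:
            member_role[m] = role

    loci: list[BisLocus] = []
    for genome, (lo, hi) in neighborhoods:
        calls = [
            GeneCall(
                p.protein_id,
                member_role.get(f"{genome.replicon_id}::{p.protein_id}", "unannotated"),
            )
            for p in genome.proteins[lo : hi + 1]
        ]
        try:
            locus = trim_locus(calls, genome.replicon_id)
        except ValueError:
            logger.info("%s: neighborhood has no annotated roles; dropped", genome.replicon_id)
            continue
        locus.complete = assess_completeness(locus)
        locus.architecture = classify_architecture(locus) if locus.complete else "unclassified"
        loci.append(locus)
    return loci
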