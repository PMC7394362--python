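"""Metatranscriptome screening: best-hit-per-read expression profiles.

Unlike the metagenome mode (which keeps all hits per read), transcript mode
retains only the best hit for each read, then normalizes per-gene counts by
sequencing depth and protein nucleotide length:
``1e9 * count / (total_reads * length_nt)`` — a reads-per-billion-scale rate
chosen so typical values are human readable; only relative comparisons are
meaningful.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .roster import BisRoster, default_roster
from .types import ExpressionProfile

EXPRESSION_SCALE = 1e9
DEFAULT_PRESENCE_THRESHOLD = 15


def best_hit_per_read(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one record per read id.

    Lowest E-value wins; ties go to the highest bit score, remaining ties to
    the lexicographically smallest subject.  Idempotent.
    """
    required = {"qseqid", "sseqid", "evalue", "bitscore"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    if len(records) == 0:
        return records.copy()
    ordered = records.sort_values(
        by=["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset="qseqid", keep="first").reset_index(drop=True)


def normalize_expression(count: int, total_reads: int, protein_length_nt: int) -> float:
    """Depth- and length-normalized expression rate (1e9 scale)."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if protein_length_nt < 3:
        raise ValueError("protein_length_nt must be >= 3")
    if count < 0:
        raise ValueError("count must be >= 0")
    return EXPRESSION_SCALE * count / (total_reads * protein_length_nt)


def expression_profile(
    records: pd.DataFrame,
    sample_id: str,
    total_reads: int,
    roster: BisRoster | None = None,
    max_evalue: float = 0.001,
) -> ExpressionProfile:
    """Best-hit counts and normalized expression for one metatranscriptome."""
    from .metagenome import filter_hits  # shared E-value cutoff semantics

    if roster is None:
        roster = default_roster()
    best = best_hit_per_read(filter_hits(records, max_evalue))
    raw = {g: 0 for g in roster.names}
    if len(best):
        for subject, n in best["sseqid"].value_counts().items():
            if subject in raw:
                raw[subject] = int(n)
    expression = {
        g: normalize_expression(raw[g], total_reads, roster.length_nt(g))
        for g in roster.names
    }
    return ExpressionProfile(
        sample_id=sample_id, total_reads=total_reads, raw_counts=raw, expression=expression
    )


def expression_presence(
    profiles: Iterable[ExpressionProfile],
    threshold_genes: int = DEFAULT_PRESENCE_THRESHOLD,
) -> tuple[int, float]:
    """(n, percent) of samples expressing >= ``threshold_genes`` roster genes."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    passing = sum(
        1
        for p in profiles
        if sum(1 for c in p.raw_counts.values() if c > 0) >= threshold_genes
    )
    return passing, 100.0 * passing / len(profiles)


def replicate_presence(
    counts_by_replicate: Mapping[str, Mapping[str, int]], min_replicates: int = 2
) -> dict[str, bool]:
    """Gene called expressed in a condition iff nonzero in >= m replicates.

    ``counts_by_replicate`` maps replicate id -> per-gene raw counts (e.g.
    three replicate cultures of one growth condition; default m = 2 of 3).
    """
    if not counts_by_replicate:
        raise ValueError("no replicates given")
    genes: set[str] = set()
    for counts in counts_by_replicate.values():
        genes.update(counts)
    return {
        g: sum(1 for c in counts_by_replicate.values() if c.get(g, 0) > 0) >= min_replicates
        for g in sorted(genes)
    }
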