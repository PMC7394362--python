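"""Donor-level prevalence of BIS genes.

Cohort individuals are usually sequenced more than once, so gene hits are
averaged by donor before any prevalence or group statistic is computed.  A
donor's presence count is the number of roster genes with a nonzero
donor-averaged hit count (equivalently: detected in any of the donor's
samples); the prevalence curve reports the percentage of donors carrying at
least k of the 18 proteins.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .roster import BisRoster, default_roster
from .types import DonorProfile, SampleHitProfile

logger = logging.getLogger(__name__)


def aggregate_by_donor(
    profiles: Iterable[SampleHitProfile],
    groups: Mapping[str, str],
    bacteroidetes: Mapping[str, float] | None = None,
    roster: BisRoster | None = None,
    length_normalize: bool = False,
) -> list[DonorProfile]:
    """Average per-gene hits over each donor's samples.

    ``groups`` maps donor_id -> health group; ``bacteroidetes`` optionally
    maps sample_id -> phylum relative abundance (percent), averaged per
    donor.  ``length_normalize`` divides mean hits by the gene's nucleotide
    length (off by default).  Samples with a donor missing from ``groups``
    are rejected.  The result is independent of sample order.
    """
    if roster is None:
        roster = default_roster()
    by_donor: dict[str, list[SampleHitProfile]] = {}
    for p in profiles:
        if p.donor_id not in groups:
            raise KeyError(f"sample {p.sample_id!r} has unknown donor {p.donor_id!r}")
        by_donor.setdefault(p.donor_id, []).append(p)

    donors: list[DonorProfile] = []
    for donor_id in sorted(by_donor):
        samples = by_donor[donor_id]
        mean_counts = {
            g: float(np.mean([s.counts.get(g, 0) for s in samples])) for g in roster.names
        }
        if length_normalize:
            mean_counts = {g: v / roster.length_nt(g) for g, v in mean_counts.items()}
        presence = sum(1 for v in mean_counts.values() if v > 0)
        bact = float("nan")
        if bacteroidetes is not None:
            vals = [bacteroidetes[s.sample_id] for s in samples if s.sample_id in bacteroidetes]
            if vals:
                bact = float(np.mean(vals))
        donors.append(
            DonorProfile(
                donor_id=donor_id,
                group=groups[donor_id],
                n_samples=len(samples),
                mean_counts=mean_counts,
                presence_count=presence,
                bacteroidetes_abundance=bact,
            )
        )
    return donors


def prevalence_distribution(donors: Iterable[DonorProfile]) -> pd.DataFrame:
    """Percent of donors with presence_count >= k (and = k), k = 0..18.

    The >=-curve is non-increasing and equals 100 at k = 0.
    """
    counts = [d.presence_count for d in donors]
    if not counts:
        raise ValueError("no donors given")
    n = len(counts)
    rows = []
    for k in range(19):
        eq = sum(1 for c in counts if c == k)
        ge = sum(1 for c in counts if c >= k)
        rows.append(
            {
                "k": k,
                "n_eq": eq,
                "percent_eq": 100.0 * eq / n,
                "n_ge": ge,
                "percent_ge": 100.0 * ge / n,
            }
        )
    return pd.DataFrame(rows)


def parse_taxonomic_profile(source) -> dict[str, float]:
    """Phylum -> relative abundance from a clade/abundance profile table.

    ``source`` is a path or file-like object with tab-separated
    ``clade<TAB>abundance`` lines in MetaPhlAn layout (rank-prefixed clade
    strings, e.g. ``k__Bacteria|p__Bacteroidetes``).  Lines starting with
    ``#`` or a header line are ignored; otherwise unparseable lines are
    rejected with their line number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    phyla: dict[str, float] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and len(parts) == 2 and parts[0].lower() in ("clade", "clade_name"):
            continue
        if len(parts) != 2:
            raise ValueError(f"unparseable profile line {lineno}: {line!r}")
        clade, raw = parts
        try:
            value = float(raw)
        except ValueError:
            raise ValueError(f"non-numeric abundance on line {lineno}: {raw!r}") from None
        last = clade.split("|")[-1]
        if last.startswith("p__"):
            phyla[last[3:]] = value
    return phyla


def bacteroidetes_abundance(source) -> float:
    """Bacteroidetes phylum percent from a profile table (0 if absent)."""
    return parse_taxonomic_profile(source).get("Bacteroidetes", 0.0)
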