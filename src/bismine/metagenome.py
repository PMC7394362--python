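"""Metagenome screening: read-hit tables -> per-sample counts and coverage scores.

A metagenome's reads are aligned against the 18 BIS proteins; records passing
the E <= 0.001 cutoff are tallied per gene ("count score"; hits are
non-mutually exclusive, so one read may count toward several genes).  The
per-sample per-gene heat value is the coverage score
``log10(1e6 * hits / total_reads + 1)``.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .roster import BisRoster, default_roster
from .types import SampleHitProfile

logger = logging.getLogger(__name__)

HIT_MAX_EVALUE = 0.001


def filter_hits(records: pd.DataFrame, max_evalue: float = HIT_MAX_EVALUE) -> pd.DataFrame:
    """Keep alignment records with E-value <= cutoff (inclusive)."""
    if "evalue" not in records.columns:
        raise ValueError("hit table lacks an 'evalue' column")
    evalues = pd.to_numeric(records["evalue"], errors="coerce")
    bad = np.flatnonzero(evalues.isna().to_numpy())
    if bad.size:
        raise ValueError(f"malformed E-value in hit table at row {int(bad[0])}")
    return records.loc[evalues.to_numpy() <= max_evalue]


def count_hits(records: pd.DataFrame, roster: BisRoster | None = None) -> dict[str, int]:
    """Per-gene tally of retained records (no best-hit selection).

    Subjects not in the roster are counted under ``"other"`` and logged.
    """
    if roster is None:
        roster = default_roster()
    counts = {g: 0 for g in roster.names}
    if len(records) == 0:
        return counts
    known = set(roster.names)
    for subject, n in records["sseqid"].value_counts().items():
        if subject in known:
            counts[subject] = int(n)
        else:
            counts["other"] = counts.get("other", 0) + int(n)
            logger.warning("subject %r not in roster; counted under 'other'", subject)
    return counts


def coverage_score(hits: int, total_reads: int) -> float:
    """``log10(1e6 * hits / total_reads + 1)``; 0 when hits = 0."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if hits < 0:
        raise ValueError("hits must be >= 0")
    return math.log10(1e6 * hits / total_reads + 1.0)


def build_score_matrix(
    profiles: Iterable[SampleHitProfile], roster: BisRoster | None = None
) -> pd.DataFrame:
    """Samples x 18 coverage-score matrix with a leading body_site column."""
    if roster is None:
        roster = default_roster()
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    rows = {}
    sites = {}
    for p in profiles:
        rows[p.sample_id] = [
            coverage_score(p.counts.get(g, 0), p.total_reads) for g in roster.names
        ]
        sites[p.sample_id] = p.body_site
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=roster.names)
    mat.index.name = "sample_id"
    mat.insert(0, "body_site", pd.Series(sites))
    return mat


def build_count_matrix(
    profiles: Iterable[SampleHitProfile], roster: BisRoster | None = None
) -> pd.DataFrame:
    """Samples x 18 raw hit-count matrix (input of the cooccurrence network)."""
    if roster is None:
        roster = default_roster()
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    mat = pd.DataFrame.from_dict(
        {p.sample_id: [int(p.counts.get(g, 0)) for g in roster.names] for p in profiles},
        orient="index",
        columns=roster.names,
    )
    mat.index.name = "sample_id"
    return mat


def site_prevalence(profiles: Iterable[SampleHitProfile]) -> pd.DataFrame:
    """Per-body-site count and percentage of samples with >= 1 roster hit."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    rows = []
    by_site: dict[str, list[SampleHitProfile]] = {}
    for p in profiles:
        by_site.setdefault(p.body_site, []).append(p)
    for site in sorted(by_site):
        group = by_site[site]
        with_hit = sum(1 for p in group if p.has_any_hit)
        rows.append(
            {
                "body_site": site,
                "n_samples": len(group),
                "n_with_hit": with_hit,
                "percent": 100.0 * with_hit / len(group),
            }
        )
    return pd.DataFrame(rows)
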