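"""Readers and writers for the pipeline's on-disk formats.

All outputs are plain text: FASTA for proteins (via Biopython), tab-separated
tables for features, alignment hits (12-column BLAST-style layout), sample
metadata, loci, score matrices, network edge/node lists, and two-column
clade/abundance taxonomic profiles.
"""

from __future__ import annotations

import os
from collections.abc import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import BLAST6_COLUMNS
from .types import AnchorHit, BisLocus, GenomeProteinTable, Protein, SampleHitProfile

FEATURE_COLUMNS = ["replicon_id", "protein_id", "start", "end", "strand", "index"]
METADATA_COLUMNS = ["sample_id", "donor_id", "group", "body_site", "total_reads"]
ANCHOR_COLUMNS = ["protein_id", "profile", "bitscore", "evalue"]
LOCUS_COLUMNS = [
    "replicon_id",
    "first_protein",
    "last_protein",
    "n_genes",
    "architecture",
    "complete",
    "roles",
]


# ---------------------------------------------------------------- genomes

def write_genome(genome: GenomeProteinTable, fasta_path, features_path) -> None:
    """Protein FASTA plus a coordinate feature table for one replicon."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="") for p in genome
    ]
    SeqIO.write(records, fasta_path, "fasta")
    rows = [
        [genome.replicon_id, p.protein_id, p.start, p.end, p.strand, p.index]
        for p in genome
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(features_path, sep="\t", index=False)


def read_genome(fasta_path, features_path) -> GenomeProteinTable:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    feats = pd.read_csv(features_path, sep="\t")
    replicons = feats["replicon_id"].unique()
    if len(replicons) != 1:
        raise ValueError(f"feature table must describe one replicon, found {len(replicons)}")
    proteins = [
        Protein(
            protein_id=row.protein_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            sequence=seqs[row.protein_id],
            index=int(row.index),
        )
        for row in feats.sort_values("index").itertuples()
    ]
    return GenomeProteinTable(replicon_id=str(replicons[0]), proteins=proteins)


# ----------------------------------------------------------- anchor hits

def write_anchor_hits(hits: Iterable[AnchorHit], path) -> None:
    rows = [[h.protein_id, h.profile_name, h.bitscore, h.evalue] for h in hits]
    pd.DataFrame(rows, columns=ANCHOR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_anchor_hits(path) -> list[AnchorHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        AnchorHit(
            protein_id=str(r.protein_id),
            bitscore=float(r.bitscore),
            evalue=float(r.evalue),
            profile_name=str(r.profile),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------- hit tables

def write_hit_table(records: pd.DataFrame, path) -> None:
    """12-column tabular alignment records, headerless like BLAST outfmt 6."""
    records.to_csv(path, sep="\t", index=False, header=False)


def read_hit_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BLAST6_COLUMNS)


# --------------------------------------------------------------- metadata

def write_metadata(profiles: Iterable[SampleHitProfile], groups, path) -> None:
    rows = [
        [p.sample_id, p.donor_id, groups[p.donor_id], p.body_site, p.total_reads]
        for p in profiles
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    return df


# -------------------------------------------------------------------- loci

def write_loci(loci: Iterable[BisLocus], path) -> None:
    rows = [
        [
            loc.replicon_id,
            loc.gene_calls[0].protein_id,
            loc.gene_calls[-1].protein_id,
            len(loc.gene_calls),
            loc.architecture,
            loc.complete,
            ",".join(loc.roles),
        ]
        for loc in loci
    ]
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def write_loci_gff3(loci: Iterable[BisLocus], genomes: dict[str, GenomeProteinTable], path) -> None:
    """Locus spans as GFF3 misc_feature records (coordinates from the genome)."""
    lines = ["##gff-version 3"]
    for k, loc in enumerate(loci):
        genome = genomes[loc.replicon_id]
        start = genome.get(loc.gene_calls[0].protein_id).start
        end = genome.get(loc.gene_calls[-1].protein_id).end
        attrs = (
            f"ID=bis_locus_{k};architecture={loc.architecture};"
            f"complete={str(loc.complete).lower()}"
        )
        lines.append(
            "\t".join(
                [loc.replicon_id, "bismine", "gene_cluster", str(start), str(end),
                 ".", "+", ".", attrs]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ------------------------------------------------------------- tax profiles

def write_taxonomic_profile(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, header=False)


def profiles_from_tables(
    metadata: pd.DataFrame, counts: pd.DataFrame
) -> list[SampleHitProfile]:
    """Reassemble SampleHitProfile objects from metadata + count matrix."""
    gene_cols = [c for c in counts.columns if c not in ("sample_id", "body_site")]
    counts = counts.set_index("sample_id") if "sample_id" in counts.columns else counts
    out = []
    for row in metadata.itertuples():
        gene_counts = {g: int(counts.loc[row.sample_id, g]) for g in gene_cols}
        out.append(
            SampleHitProfile(
                sample_id=str(row.sample_id),
                donor_id=str(row.donor_id),
                body_site=str(row.body_site),
                total_reads=int(row.total_reads),
                counts=gene_counts,
            )
        )
    return out


def checksum(path) -> str:
    """SHA-256 of a file, for run manifests."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def list_files(directory, suffix: str) -> list[str]:
    return sorted(
        os.path.join(directory, f) for f in os.listdir(directory) if f.endswith(suffix)
    )
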