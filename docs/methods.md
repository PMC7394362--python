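# Methods

This note documents the models, parameter choices and numerical conventions
behind `bismine`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Locus mining

Candidate BIS clusters are found by anchor-and-expand: any protein with a
sheath-profile hit above the gathering threshold (bit score strictly >
31.4 **and** E-value strictly < 1e-9) seeds a neighborhood of up to 20
proteins on either side of the anchor, clipped at replicon ends. The
profile search itself is external — the module consumes a tabular hit file
(or the synthetic generator's equivalent); re-implementing profile-HMM
scoring is out of proportion to its role here. Neighborhoods from several
anchors on one replicon are merged before trimming so that a single
physical locus (e.g. one carrying two sheath genes) is reported once.

### Pairwise identity

Identity is computed on a Needleman–Wunsch global alignment (match +2,
mismatch −1, gap −2 per residue, terminal gaps penalized) as identical
aligned pairs divided by the length of the shorter sequence. Among all
score-optimal alignments, the one with the most identical pairs defines
the value; the dynamic program carries (score, identities) pairs
lexicographically, which makes the quantity well defined and symmetric.
Scoring parameters are configurable.

A caveat documented here because it shaped the generator: with the
shorter-sequence denominator, score-optimal alignments of *unrelated*
random proteins reach ~0.23 identity at equal lengths and >0.5 once
lengths differ by more than ~1.6× (the forced gaps let matches scatter
freely along the longer sequence). Identity over the shorter sequence is
therefore only discriminative between sequences of comparable length.

### Clustering, annotation, trimming, classification

Pooled neighborhood proteins are processed in decreasing length order
(ties broken by ascending protein id, for determinism) and each joins the
earliest-founded centroid at ≥ 50% identity, else founds a new cluster —
the greedy centroid strategy of UCLUST-style tools. Clusters with ≥ 4
members are kept. Because cluster sizes must clear that filter, locus
mining is designed to run on a *batch* of genomes (as in a multi-genome
survey); a single genome in isolation cannot populate 4-member clusters.

Cluster representatives are annotated by best-hit global alignment against
the 18 roster reference sequences. A hit annotates when the alignment
score is strictly positive, identity ≥ 0.4 over the shorter sequence, and
≥ 50% of the shorter sequence is aligned; members inherit their centroid's
role. The positive-score requirement does most of the work: true homologs
(≤ ~20% diverged) score strongly positive while unrelated pairs score
strongly negative, a far sharper separation than any identity cutoff
alone (unrelated-pair identity reaches ~0.43 within the generator's
length band).

Loci are trimmed to the span bounded by the outermost DUF4255 and
FtsH/ATPase calls (inclusive), the conserved boundary genes of the
cluster; when either boundary role is absent the span runs from the first
to the last annotated role. A locus is **complete** when it carries at
least one call of each core role: baseplate gp25, gp27 and gp6, sheath,
tube, and the FtsH/ATPase. Complete loci are classified in rule order:
architecture 3 if the FtsH/ATPase call precedes the DUF4157 call (the
inverted pair of the compact form), else architecture 1 with ≥ 2 sheath
and ≥ 2 tube calls, else architecture 2 with exactly one sheath call.
Classification uses gene order only; strand is ignored because the
conserved arrangements are defined by order, and per-gene strand of the
real loci is not available to the classifier.

## Metagenome screening

Alignment records are kept at E ≤ 0.001 (inclusive; the cutoff's
strictness is not specified by convention, so ≤ is used and configurable).
All retained hits count — one read may contribute to several genes
("non-mutually exclusive"), matching how short reads hit homologous gene
families. The per-sample per-gene coverage score is
`log10(1e6 · hits/total_reads + 1)`: zero when hits are zero, strictly
increasing in hits, invariant under proportional scaling of hits and
reads. Inverting the transform recovers the raw counts exactly, which the
tests assert as a round-trip property.

## Cooccurrence network

For every unordered pair of roster genes the running total of
`min(count_a, count_b)` across samples defines the edge weight; column
sums define node weights. Weights use raw filtered counts, not coverage
scores — a running total of transformed scores would lose the count
interpretation and break the `weight ≤ min(node totals)` invariant. All
153 pairs of the 18-gene roster are defined; zero-weight edges may be
dropped on export only. No significance is attached to edges.

## Donor prevalence

Hits are averaged per donor across that donor's samples, making each
individual count once regardless of sequencing depth or sample count.
The presence count is the number of roster genes with nonzero
donor-averaged hits — identical to "detected in any sample", since means
of non-negative counts are positive iff any count is (asserted as a
cross-check). *Bacteroidetes* abundance is the phylum-level row of a
clade/abundance taxonomic profile, averaged per donor with the mean (the
aggregation statistic is not dictated by anything upstream; the mean is
consistent with how hit counts are aggregated). IBD subgroups (Crohn's,
colitis) keep their labels through aggregation and merge into "IBD" only
at comparison time. Optional per-gene length normalization (mean hits /
gene nucleotide length) is off by default.

## Group comparison

The primary statistic is `median(a) − median(b)` with a two-sided
percentile bootstrap: each of 10,000 replicates resamples both groups
independently, with replacement, at their original sizes; the CI is the
(2.5, 97.5) percentile pair (linear interpolation between order
statistics), and an interval excluding zero is significant. Donor-level
values are the resampling unit — inputs are already donor-normalized, so
resampling raw samples would double-count individuals. One seeded
generator per call makes every result bit-reproducible; the seed is
recorded in the result.

Validation uses the asymptotic Wilcoxon rank-sum test: midranks for ties,
tie-corrected variance, normal approximation with a 0.5 continuity
correction (the default in the standard R implementation). Without the
correction the approximation misses the exact permutation p by up to
~0.15 at group sizes of 2–4; with it, agreement is within 0.09 for
continuous data across all n ≤ 7 (measured over 3000 instances). For
*heavily tied* tiny samples no asymptotic approximation is accurate to
0.1 — tie handling is instead verified exactly against an independent
implementation. No multiple-testing correction is applied; the four
comparisons are reported as-is.

**Known limitation — discrete metrics.** Donor presence counts are
integers in 0..18. The bootstrap distribution of a median difference of
integer data is lumpy, and when the count distribution is flat near the
group medians the replicate distribution carries an atom at exactly 0.
With a planted shift of +2 (noise sd 2.5, 100 donors/group) the 2.5th
percentile lands exactly on 0 in roughly one run in six, which the
CI-excludes-zero rule scores as non-significant even though the rank-sum
test rejects at p < 1e-3 in those same runs. This is an inherent property
of percentile bootstraps on discrete medians, not an implementation
artifact; on continuous metrics (e.g. phylum abundance) the same engine
achieves ~95% CI coverage and ~4% null significance (criterion-style
checks in the test suite and acceptance script).

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with the statistical structure
the analysis assumes:

* **Genomes.** Planted loci follow the three architecture templates; locus
  proteins are copies of the deterministic roster references with 5–18% of
  positions substituted, so within-role identity stays above the 50%
  clustering threshold and between-role identity below it by
  construction. Architecture 3 carries shortened gp27/gp6 (85%) and is
  laid down in mirrored orientation, realizing the inverted
  FtsH/ATPase–DUF4157 pair in gene order. Flanking proteins are mutated
  copies drawn from a fixed pool of 30 decoy families, emulating
  paralogous gene families; all lengths sit in a 130–185 aa band so the
  shorter-sequence identity denominator stays discriminative (see above).
  These are scaled-down stand-ins: real sheath or ATPase proteins are
  several hundred residues, and real loci carry insertions, pseudogenes
  and strand structure the generator omits.
* **Cohorts.** Each donor carries a random subset of the 18 genes whose
  size is drawn as round(Normal(12, 2.5)) clipped to 0..18, core-ten genes
  weighted 3:1 over peripheral ones; the healthy-vs-IBD effect subtracts
  the planted shift from the IBD subgroups' carriage mean, so the planted
  median difference is recoverable by direct computation (the ±1 recovery
  property in the tests). Carried genes get negative-binomial per-sample
  counts (core mean 3.0, peripheral 1.2, dispersion 2.0 — overdispersed
  with realistic zeros at low means) and are guaranteed detection in at
  least one of the donor's 1–3 samples; non-carried genes stay at zero.
  Total reads are log-normal around 2 million. Real cohorts add
  compositional coupling between genes, batch effects and uneven depth
  none of which are modelled — passing tests show the pipeline's
  arithmetic and inference are correct, not that the biological effect
  exists.
* **Hit tables.** True hits draw E-values log-uniform in [1e-30, 1e-3],
  decoys in (1e-3, 10], straddling the screening cutoff cleanly so filter
  behavior is exact by construction.
* **Taxonomic profiles.** Per-sample Bacteroidetes percent is Beta-drawn
  per group (default Beta(8, 6), ~57% mean, gut-like); remaining phyla
  split the residual by a Dirichlet draw; each rank sums to 100.

## Numerical and reproducibility conventions

Every stochastic routine takes an explicit integer seed and uses one named
`numpy` generator; derived seeds come from `SeedSequence` spawning and stay
below 2^31. Fixed seed implies bit-identical outputs, asserted for
generators, bootstrap and the CLI (byte-identical files on re-run;
manifests record parameters, package version and input checksums, with
checksum keys relative to the output directory). Problem sizes used by the
default test run and the acceptance script — 20 genomes per architecture
batch, 500 calibration cohorts at 1,000 bootstrap replicates, 50
end-to-end cohorts at the full 10,000 replicates — were chosen to exercise
every stage at statistically meaningful scale on a single CPU.
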