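"""Mine synthetic genomes for BIS gene clusters and classify architectures.

Generates a batch of genomes with planted loci (plus negative controls),
runs sheath-anchor neighborhood extraction, greedy 50%-identity clustering,
role annotation, trimming and architecture classification, and prints what
was found.
"""

from collections import Counter

from bismine import find_loci
from bismine.synthetic import generate_anchor_hits, generate_genome

genomes, anchors = [], {}
for label in ("1", "2", "3", "none", "decoy"):
    for s in range(5):
        g = generate_genome(label, flank_genes=25, seed=s)
        genomes.append(g)
        anchors[g.replicon_id] = generate_anchor_hits(g, seed=s)

loci = find_loci(genomes, anchors)
complete = [l for l in loci if l.complete]
print(f"{len(genomes)} genomes -> {len(loci)} candidate loci, {len(complete)} complete")
print("architectures:", dict(Counter(l.architecture for l in complete)))
# Each of the 15 genomes with a planted locus yields exactly one complete
# locus of the planted architecture; the 10 control genomes yield none.
example = next(l for l in complete if l.architecture == "3")
print("architecture-3 role order:", " ".join(example.roles))
# The FtsH/ATPase call precedes DUF4157 -- the inverted pair that defines
# the compact third architecture.
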