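from collections import Counter

import numpy as np
import pytest

from bismine.cluster_finder import (
    annotate_roles,
    assess_completeness,
    classify_architecture,
    extract_neighborhood,
    filter_anchor_hits,
    filter_clusters,
    find_loci,
    greedy_cluster,
    trim_locus,
)
from bismine.roster import random_protein
from bismine.synthetic import generate_genome
from bismine.types import AnchorHit, BisLocus, GeneCall, ProteinCluster
from conftest import make_batch, random_seqs
from oracles import anchor_filter_oracle, greedy_cluster_oracle


def _hit(pid="p1", bitscore=100.0, evalue=1e-20):
    return AnchorHit(protein_id=pid, bitscore=bitscore, evalue=evalue)


class TestAnchorFilter:
    def test_gathering_threshold_is_strict(self):
        # a hit exactly at bit score 31.4 is below the ">" threshold
        assert filter_anchor_hits([_hit(bitscore=31.4, evalue=1e-12)]) == []
        assert len(filter_anchor_hits([_hit(bitscore=100, evalue=1e-20)])) == 1
        assert filter_anchor_hits([_hit(bitscore=100, evalue=1e-9)]) == []

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        hits = [
            _hit(f"p{i}", float(rng.uniform(0, 100)), float(10.0 ** rng.uniform(-20, 0)))
            for i in range(1000)
        ]
        got = filter_anchor_hits(hits)
        assert got == anchor_filter_oracle(hits, 31.4, 1e-9)


class TestNeighborhood:
    def test_clipping_and_exact_window(self):
        g = generate_genome("none", flank_genes=100, seed=1)
        first = g.proteins[0].protein_id
        assert len(extract_neighborhood(g, first, 20)) == 21  # left side clipped
        mid = g.proteins[50].protein_id
        assert len(extract_neighborhood(g, mid, 20)) == 41
        assert extract_neighborhood(g, mid, 0) == [g.proteins[50]]

    def test_absent_anchor_rejected(self):
        g = generate_genome("none", flank_genes=5, seed=1)
        with pytest.raises(KeyError, match="nope"):
            extract_neighborhood(g, "nope")


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        clusters = greedy_cluster([(f"p{i}", "MKTAYIAKQR") for i in range(5)])
        assert len(clusters) == 1 and clusters[0].size == 5

    def test_divergent_families_stay_separate(self):
        rng = np.random.default_rng(9)
        fam_a = random_protein(40, rng)
        fam_b = random_protein(40, rng)
        clusters = greedy_cluster([("a1", fam_a), ("a2", fam_a), ("b1", fam_b)])
        assert {frozenset(c.member_ids) for c in clusters} == {
            frozenset({"a1", "a2"}),
            frozenset({"b1"}),
        }

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prots = [(f"p{i}", s) for i, s in enumerate(random_seqs(rng, 12, 3, 10))]
        got = {frozenset(c.member_ids) for c in greedy_cluster(prots)}
        expected = set(greedy_cluster_oracle(prots, 0.5))
        assert got == expected

    def test_partition_and_order_insensitivity(self):
        rng = np.random.default_rng(4)
        prots = [(f"p{i}", s) for i, s in enumerate(random_seqs(rng, 15, 3, 10))]
        clusters = greedy_cluster(prots)
        all_members = [m for c in clusters for m in c.member_ids]
        assert sorted(all_members) == sorted(p for p, _ in prots)
        shuffled = list(prots)
        rng.shuffle(shuffled)
        again = greedy_cluster(shuffled)
        assert {frozenset(c.member_ids) for c in clusters} == {
            frozenset(c.member_ids) for c in again
        }


def test_filter_clusters_threshold():
    clusters = [
        ProteinCluster(centroid_id="a", member_ids=["a"] + [f"x{i}" for i in range(n - 1)])
        for n in (5, 4, 3, 1)
    ]
    # fix member uniqueness for centroid invariant
    assert [c.size for c in filter_clusters(clusters)] == [5, 4]
    assert [c.size for c in filter_clusters(clusters, min_size=1)] == [5, 4, 3, 1]
    with pytest.raises(ValueError):
        filter_clusters(clusters, min_size=0)


class TestAnnotateRoles:
    def test_reference_copy_gets_its_role(self, roster):
        rep = roster.reference_sequences["Sheath1"]
        roles = annotate_roles({"r1": rep}, roster)
        assert roles["r1"] == "sheath"

    def test_unrelated_sequence_unannotated(self, roster):
        rng = np.random.default_rng(1)
        roles = annotate_roles({"r1": random_protein(150, rng)}, roster)
        assert roles["r1"] == "unannotated"

    def test_planted_genome_roles_recovered(self, roster):
        g = generate_genome("1", flank_genes=0, seed=2)
        reps = {p.protein_id: p.sequence for p in g}
        roles = annotate_roles(reps, roster)
        planted = g.attrs["planted"]
        for pid, gene in planted.items():
            assert roles[pid] == roster.role_of(gene), (pid, gene)


def _calls(roles):
    return [GeneCall(f"p{i}", r) for i, r in enumerate(roles)]


class TestTrimAndClassify:
    def test_trim_between_boundary_roles(self):
        calls = _calls(
            ["unannotated", "duf4255", "hypothetical", "sheath", "ftsh_atpase", "unannotated"]
        )
        locus = trim_locus(calls, "rep")
        assert [c.role for c in locus.gene_calls] == [
            "duf4255", "hypothetical", "sheath", "ftsh_atpase"
        ]

    def test_trim_fallback_without_boundary_roles(self):
        calls = _calls(["unannotated", "sheath", "tube", "unannotated"])
        locus = trim_locus(calls, "rep")
        assert [c.role for c in locus.gene_calls] == ["sheath", "tube"]

    def test_trim_rejects_fully_unannotated(self):
        with pytest.raises(ValueError):
            trim_locus(_calls(["unannotated", "unannotated"]), "rep")

    def test_all_roles_present_keeps_all(self):
        roles = ["duf4255"] + ["sheath", "tube", "lysm"] + ["ftsh_atpase"]
        locus = trim_locus(_calls(roles), "rep")
        assert len(locus.gene_calls) == 5

    def test_completeness_rules(self):
        complete = _calls(
            ["duf4255", "sheath", "tube", "baseplate_gp25", "baseplate_gp27",
             "baseplate_gp6", "ftsh_atpase"]
        )
        locus = BisLocus("rep", complete)
        assert assess_completeness(locus)
        missing_gp6 = BisLocus("rep", [c for c in complete if c.role != "baseplate_gp6"])
        assert not assess_completeness(missing_gp6)
        lone_sheath = BisLocus("rep", _calls(["sheath"]))
        assert not assess_completeness(lone_sheath)

    def test_architecture_rules(self):
        base = ["duf4255", "sheath", "sheath", "tube", "tube", "baseplate_gp25",
                "baseplate_gp27", "baseplate_gp6", "duf4157", "ftsh_atpase"]
        assert classify_architecture(BisLocus("r", _calls(base))) == "1"
        single = ["duf4255", "sheath", "tube", "tube", "baseplate_gp25",
                  "baseplate_gp27", "baseplate_gp6", "duf4157", "ftsh_atpase"]
        assert classify_architecture(BisLocus("r", _calls(single))) == "2"
        inverted = ["ftsh_atpase", "duf4157", "baseplate_gp6", "baseplate_gp27",
                    "baseplate_gp25", "tube", "sheath", "duf4255"]
        assert classify_architecture(BisLocus("r", _calls(inverted))) == "3"
        incomplete = BisLocus("r", _calls(["sheath", "tube"]))
        assert classify_architecture(incomplete) == "unclassified"


class TestEndToEnd:
    @pytest.mark.parametrize("arch", ["1", "2", "3"])
    def test_planted_architecture_recovered(self, arch):
        genomes, anchors = make_batch(arch, n=6)
        loci = find_loci(genomes, anchors)
        complete = [l for l in loci if l.complete]
        assert len(complete) == 6
        assert Counter(l.architecture for l in complete) == {arch: 6}

    @pytest.mark.parametrize("label", ["none", "decoy"])
    def test_negative_controls_yield_no_complete_locus(self, label):
        genomes, anchors = make_batch(label, n=6)
        loci = find_loci(genomes, anchors)
        assert all(not l.complete for l in loci)
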