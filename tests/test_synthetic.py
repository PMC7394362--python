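import numpy as np
import pytest

from bismine.roster import default_roster
from bismine.synthetic import (
    ARCHITECTURE_TEMPLATES,
    CohortSpec,
    generate_alignment_hits,
    generate_anchor_hits,
    generate_cohort,
    generate_genome,
    generate_taxonomic_profiles,
)


class TestGenomes:
    def test_architecture1_has_two_sheaths_two_tubes(self, roster):
        g = generate_genome("1", flank_genes=25, seed=7)
        roles = [roster.role_of(name) for name in g.attrs["planted"].values()]
        assert roles.count("sheath") == 2
        assert roles.count("tube") == 2

    def test_none_plants_nothing(self):
        g = generate_genome("none", flank_genes=25, seed=7)
        assert g.attrs["planted"] == {}

    def test_architecture3_inverts_ftsh_duf4157(self):
        g = generate_genome("3", flank_genes=0, seed=1)
        names = [g.attrs["planted"][p.protein_id] for p in g]
        assert names.index("FtsH/ATPase") < names.index("DUF4157")
        assert ARCHITECTURE_TEMPLATES["1"].index("DUF4157") < ARCHITECTURE_TEMPLATES[
            "1"
        ].index("FtsH/ATPase")

    def test_decoy_has_lone_sheath_like_gene(self):
        g = generate_genome("decoy", flank_genes=10, seed=3)
        assert list(g.attrs["planted"].values()) == ["SheathLike"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            generate_genome("4")

    def test_deterministic_under_seed(self):
        a = generate_genome("2", flank_genes=10, seed=5)
        b = generate_genome("2", flank_genes=10, seed=5)
        assert [(p.protein_id, p.start, p.sequence) for p in a] == [
            (p.protein_id, p.start, p.sequence) for p in b
        ]
        c = generate_genome("2", flank_genes=10, seed=6)
        assert [p.sequence for p in a] != [p.sequence for p in c]

    def test_templates_pairwise_distinguishable(self):
        seqs = {k: tuple(v) for k, v in ARCHITECTURE_TEMPLATES.items()}
        assert len(set(seqs.values())) == 3

    def test_anchor_hits_mark_planted_sheaths(self, roster):
        g = generate_genome("1", flank_genes=10, seed=2)
        hits = generate_anchor_hits(g, seed=2)
        passing = [h for h in hits if h.bitscore > 31.4 and h.evalue < 1e-9]
        sheaths = {
            pid for pid, name in g.attrs["planted"].items()
            if roster.role_of(name) == "sheath"
        }
        assert {h.protein_id for h in passing} == sheaths
        assert len(hits) > len(passing)  # spurious sub-threshold hits included


class TestCohort:
    def test_null_configuration_has_no_planted_shift(self):
        spec = CohortSpec(
            n_donors_per_group={"healthy": 50, "ibd_cd": 25, "ibd_uc": 25},
            median_shift=0.0,
            seed=3,
        )
        _, donors = generate_cohort(spec)
        h = np.median([d.presence_count for d in donors if d.group == "healthy"])
        i = np.median([d.presence_count for d in donors if d.group.startswith("ibd")])
        assert abs(h - i) <= 1

    def test_planted_shift_recovered_within_one(self):
        spec = CohortSpec(
            n_donors_per_group={"healthy": 100, "ibd_cd": 50, "ibd_uc": 50},
            median_shift=2.0,
            seed=3,
        )
        _, donors = generate_cohort(spec)
        h = np.median([d.presence_count for d in donors if d.group == "healthy"])
        i = np.median([d.presence_count for d in donors if d.group.startswith("ibd")])
        assert abs((h - i) - 2.0) <= 1

    def test_samples_per_donor_within_range(self, small_cohort):
        spec, profiles, donors = small_cohort
        lo, hi = spec.samples_per_donor
        per_donor = {}
        for p in profiles:
            per_donor[p.donor_id] = per_donor.get(p.donor_id, 0) + 1
        assert set(per_donor) == {d.donor_id for d in donors}
        assert all(lo <= n <= hi for n in per_donor.values())

    def test_carried_genes_always_detected(self, small_cohort):
        _, profiles, donors = small_cohort
        by_donor = {}
        for p in profiles:
            by_donor.setdefault(p.donor_id, []).append(p)
        for d in donors:
            detected = {
                g for g in d.carried
                if any(s.counts[g] > 0 for s in by_donor[d.donor_id])
            }
            assert detected == set(d.carried)
            assert d.presence_count == len(d.carried)

    def test_empty_group_map_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_donors_per_group={})

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown groups"):
            CohortSpec(n_donors_per_group={"martians": 5})

    def test_deterministic_under_seed(self):
        spec = dict(n_donors_per_group={"healthy": 5, "ibd_cd": 5}, seed=9)
        p1, d1 = generate_cohort(CohortSpec(**spec))
        p2, d2 = generate_cohort(CohortSpec(**spec))
        assert [(p.sample_id, p.total_reads, p.counts) for p in p1] == [
            (p.sample_id, p.total_reads, p.counts) for p in p2
        ]
        assert [(d.donor_id, d.carried) for d in d1] == [(d.donor_id, d.carried) for d in d2]


class TestAlignmentHits:
    def test_zero_counts_give_empty_table(self, roster, small_cohort):
        _, profiles, _ = small_cohort
        p = profiles[0]
        empty = type(p)(
            sample_id="z", donor_id=p.donor_id, body_site="gut",
            total_reads=1000, counts={g: 0 for g in roster.names},
        )
        table = generate_alignment_hits(empty, roster, decoy_rate=0.0, seed=1)
        assert len(table) == 0

    def test_exactly_planted_counts_pass_cutoff(self, roster, small_cohort):
        _, profiles, _ = small_cohort
        p = profiles[0]
        table = generate_alignment_hits(p, roster, decoy_rate=0.5, seed=2)
        passing = table[table["evalue"] <= 0.001]
        for gene in roster.names:
            assert (passing["sseqid"] == gene).sum() == p.counts[gene]
        assert (table["evalue"] > 0.001).sum() == round(0.5 * sum(p.counts.values()))

    def test_byte_identical_reproducibility(self, roster, small_cohort):
        _, profiles, _ = small_cohort
        p = profiles[1]
        t1 = generate_alignment_hits(p, roster, decoy_rate=0.3, seed=4)
        t2 = generate_alignment_hits(p, roster, decoy_rate=0.3, seed=4)
        assert t1.to_csv(sep="\t", index=False) == t2.to_csv(sep="\t", index=False)


class TestTaxonomicProfiles:
    def test_phylum_rows_sum_to_100(self, small_cohort):
        spec, _, donors = small_cohort
        tables = generate_taxonomic_profiles(donors[:10], spec)
        for sample_id, table in tables.items():
            phyla = table[table["clade"].str.contains(r"\|p__")]
            assert phyla["abundance"].sum() == pytest.approx(100.0, abs=1e-6)
            b = phyla[phyla["clade"].str.endswith("Bacteroidetes")]["abundance"].iloc[0]
            assert 0.0 <= b <= 100.0

    def test_symmetric_beta_centers_near_fifty(self):
        spec = CohortSpec(
            n_donors_per_group={"healthy": 200},
            bacteroidetes_model={"healthy": (5.0, 5.0)},
            samples_per_donor=(1, 1),
            seed=21,
        )
        _, donors = generate_cohort(spec)
        mean = np.mean([d.bacteroidetes_abundance for d in donors])
        assert mean == pytest.approx(50.0, abs=3.0)

    def test_same_seed_identical_tables(self, small_cohort):
        spec, _, donors = small_cohort
        t1 = generate_taxonomic_profiles(donors[:3], spec)
        t2 = generate_taxonomic_profiles(donors[:3], spec)
        for k in t1:
            assert t1[k].equals(t2[k])

    def test_empty_cohort_rejected(self, small_cohort):
        spec, _, _ = small_cohort
        with pytest.raises(ValueError):
            generate_taxonomic_profiles([], spec)
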