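"""Identity clustering, consensus building, and collapse detection."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylofate import (
    build_consensus,
    cluster_at_identity,
    detect_collapse,
    identity_sweep,
    pairwise_overlap,
)
from phylofate.cluster import _merges, split_polymorphic_contig, species_assembly
from phylofate.simulate import ReadRecord

from conftest import mutate, random_seq


class TestPairwiseOverlap:
    def test_identical_sequences(self, rng):
        a = random_seq(rng, 100)
        assert pairwise_overlap(a, a) == (100, 100.0)

    def test_three_substitutions_give_97_percent(self, rng):
        a = random_seq(rng, 100)
        b = mutate(a, [20, 50, 80])
        overlap, identity = pairwise_overlap(a, b)
        assert overlap == 100
        assert identity == pytest.approx(97.0)

    def test_unrelated_sequences_no_overlap(self, rng):
        a = random_seq(rng, 120)
        b = random_seq(rng, 120)
        overlap, identity = pairwise_overlap(a, b, min_overlap=40)
        assert overlap == 0 and identity == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_overlap("", "ACGT")

    def test_staggered_overlap_found(self, rng):
        tx = random_seq(rng, 600)
        a, b = tx[:400], tx[200:]
        overlap, identity = pairwise_overlap(a, b)
        assert overlap == 200
        assert identity == 100.0


def brute_force_clusters(seqs, threshold, min_overlap):
    """Independent oracle: transitive closure over the pairwise predicate."""
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if _merges(seqs[i], seqs[j], threshold, min_overlap):
                g.add_edge(i, j)
    return sorted(sorted(c) for c in nx.connected_components(g))


class TestClusterAtIdentity:
    def test_identical_sequences_one_cluster(self, rng):
        seqs = [random_seq(rng, 200)] * 10
        assert len(cluster_at_identity(seqs, 99)) == 1

    def test_homeolog_groups_split_at_97_not_95(self, rng):
        # two groups differing at 3 sites per 100 bp (15 diffs over 500 bp)
        base = random_seq(rng, 500)
        other = mutate(base, list(range(10, 460, 30)))
        seqs = [base] * 5 + [other] * 5
        assert len(cluster_at_identity(seqs, 95)) == 1
        assert len(cluster_at_identity(seqs, 97)) == 2

    def test_matches_brute_force_closure(self, rng):
        seqs = []
        for _ in range(4):
            base = random_seq(rng, 300)
            seqs.append(base)
            seqs.append(mutate(base, list(rng.choice(300, size=9,
                                                     replace=False))))
            seqs.append(base[:150])
        for t in (80.0, 95.0, 97.0):
            ours = cluster_at_identity(seqs, t)
            assert ours == brute_force_clusters(seqs, t, 40)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(order=st.permutations(list(range(9))))
    def test_partition_is_order_invariant(self, order):
        rng = np.random.default_rng(7)
        base = [random_seq(rng, 200) for _ in range(3)]
        seqs = [mutate(b, [10 * (k + 1)]) for b in base for k in range(3)]
        ids = [f"s{i}" for i in range(len(seqs))]
        ref = {
            frozenset(c)
            for c in cluster_at_identity(seqs, 95, ids=ids)
        }
        shuffled = [seqs[i] for i in order]
        sids = [ids[i] for i in order]
        got = {
            frozenset(c)
            for c in cluster_at_identity(shuffled, 95, ids=sids)
        }
        assert got == ref

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            cluster_at_identity(["ACGT" * 20], 40)


class TestIdentitySweep:
    def test_constant_for_invariant_input(self, rng):
        seqs = [random_seq(rng, 300)] * 6
        counts = identity_sweep(seqs, [75, 80, 85, 90, 95, 97, 99])
        assert set(counts.values()) == {1}

    def test_synthetic_polyploid_splits_at_97(self, rng):
        base = random_seq(rng, 500)
        groups = []
        for _ in range(3):  # three genes, each with 3%-diverged homeologs
            g = random_seq(rng, 500)
            groups += [g] * 4 + [mutate(g, list(rng.choice(
                500, size=15, replace=False)))] * 4
        counts = identity_sweep(groups, [95, 97])
        assert counts[97] > counts[95]

    def test_counts_monotone_in_threshold(self, rng):
        seqs = []
        for _ in range(5):
            b = random_seq(rng, 250)
            seqs += [b, mutate(b, list(rng.choice(250, size=6,
                                                  replace=False)))]
        thresholds = [75, 85, 90, 95, 97, 99]
        counts = identity_sweep(seqs, thresholds)
        values = [counts[t] for t in thresholds]
        assert values == sorted(values)

    def test_thresholds_must_be_sorted(self):
        with pytest.raises(ValueError):
            identity_sweep(["ACGT" * 30], [97, 95])


class TestBuildConsensus:
    def test_single_read(self, rng):
        seq = random_seq(rng, 100)
        contig = build_consensus([("r1", seq)])
        assert contig.consensus == seq
        assert contig.depth_profile == [1] * 100

    def test_majority_base_wins(self, rng):
        seq = random_seq(rng, 120)
        variant = mutate(seq, [60])
        members = [(f"r{i}", seq) for i in range(9)] + [("rx", variant)]
        contig = build_consensus(members)
        assert contig.consensus == seq
        assert contig.depth_profile[60] == 10

    def test_tie_breaks_by_base_order(self):
        seq_a = "GGGGGAGGGGG"
        seq_c = "GGGGGCGGGGG"  # differs at position 5: A vs C
        members = [(f"a{i}", seq_a) for i in range(5)] + [
            (f"c{i}", seq_c) for i in range(5)
        ]
        contig = build_consensus(members)
        assert contig.consensus[5] == "A"

    def test_staggered_reads_reassemble_transcript(self, rng):
        tx = random_seq(rng, 700)
        members = [
            (f"r{i}", tx[s : s + 300])
            for i, s in enumerate(range(0, 401, 50))
        ]
        contig = build_consensus(members)
        assert contig.consensus == tx
        assert len(contig.members) == len(members)


def _reads(species, seqs, prefix):
    return [
        ReadRecord(id=f"{prefix}{i}", species=species, sequence=s)
        for i, s in enumerate(seqs)
    ]


class TestDetectCollapse:
    def _contig(self, seq, n_reads=12):
        from phylofate.cluster import build_consensus

        contig = build_consensus(
            [(f"p{i}", seq) for i in range(n_reads)],
            contig_id="polyploid_c00000", species="polyploid",
        )
        return contig

    def test_identical_parents_non_distinguishable(self, rng):
        seq = random_seq(rng, 300)
        contig = self._contig(seq)
        reads = {
            "polyploid": _reads("polyploid", [seq] * 12, "p"),
            "parent_s": _reads("parent_s", [seq] * 10, "s"),
            "parent_t": _reads("parent_t", [seq] * 10, "t"),
        }
        snps, report = detect_collapse([contig], reads)
        row = report.iloc[0]
        assert row["class"] == "non_distinguishable"
        assert row.n_interparent_snps == 0

    def test_fixed_difference_is_interparent_snp(self, rng):
        seq = random_seq(rng, 300)
        seq_t = mutate(seq, [150])
        contig = self._contig(seq)
        reads = {
            "polyploid": _reads("polyploid", [seq] * 12, "p"),
            "parent_s": _reads("parent_s", [seq] * 10, "s"),
            "parent_t": _reads("parent_t", [seq_t] * 10, "t"),
        }
        snps, report = detect_collapse([contig], reads)
        row = report.iloc[0]
        assert row["class"] == "parent_distinguishable"
        assert row.n_interparent_snps == 1
        assert not row.polyploid_polymorphic
        snp = snps[snps.interparent_snp].iloc[0]
        assert snp.position == 150

    def test_mixed_polyploid_reads_flag_polymorphic(self, rng):
        seq = random_seq(rng, 300)
        seq_t = mutate(seq, [150])
        contig = build_consensus(
            [(f"p{i}", seq) for i in range(6)]
            + [(f"q{i}", seq_t) for i in range(6)],
            contig_id="polyploid_c00000", species="polyploid",
        )
        reads = {
            "polyploid": _reads("polyploid", [seq] * 6 + [seq_t] * 6, "p"),
            "parent_s": _reads("parent_s", [seq] * 10, "s"),
            "parent_t": _reads("parent_t", [seq_t] * 10, "t"),
        }
        _, report = detect_collapse([contig], reads)
        assert bool(report.iloc[0].polyploid_polymorphic)

    def test_species_without_reads_is_no_coverage(self, rng):
        seq = random_seq(rng, 300)
        contig = self._contig(seq)
        reads = {
            "polyploid": _reads("polyploid", [seq] * 12, "p"),
            "parent_s": _reads("parent_s", [seq] * 10, "s"),
            "parent_t": [],
        }
        snps, report = detect_collapse([contig], reads)
        assert report.iloc[0]["class"] == "non_distinguishable"


class TestPhasingSplit:
    def test_collapsed_contig_splits_into_haplotypes(self, rng):
        tx = random_seq(rng, 500)
        tx2 = mutate(tx, list(range(20, 500, 35)))  # ~3% divergence
        reads = []
        starts = list(range(0, 301, 25))
        for i, s in enumerate(starts):
            reads.append((f"h1_{i}", tx[s : s + 200]))
            reads.append((f"h2_{i}", tx2[s : s + 200]))
        contig = build_consensus(reads, contig_id="c", species="polyploid")
        out = split_polymorphic_contig(contig)
        assert len(out) == 2
        groups = [
            {m.split("_")[0] for m in c.members} for c in out
        ]
        assert groups[0] != groups[1]
        assert all(len(g) == 1 for g in groups)  # perfectly phased
        assert {out[0].consensus, out[1].consensus} == {tx[:500], tx2[:500]}

    def test_clean_contig_not_split(self, rng):
        seq = random_seq(rng, 300)
        contig = build_consensus(
            [(f"r{i}", seq) for i in range(10)], contig_id="c",
            species="polyploid",
        )
        assert split_polymorphic_contig(contig) == [contig]


class TestSpeciesAssembly:
    def test_assembles_one_contig_per_gene(self, rng):
        genes = [random_seq(rng, 600) for _ in range(3)]
        reads = []
        n = 0
        for g in genes:
            for s in range(0, 301, 30):
                reads.append(ReadRecord(f"r{n}", "parent_s", g[s : s + 300]))
                n += 1
        contigs, membership = species_assembly(reads, "parent_s")
        assert len(contigs) == 3
        assert len(membership) == len(reads)
        assert sorted(c.consensus for c in contigs) == sorted(genes)
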