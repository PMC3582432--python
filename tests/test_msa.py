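"""Cluster alignment, quality filters, pruning, outgroup attachment."""

import pytest

from phylofate import (
    ClusterAlignment,
    align_cluster,
    attach_outgroup,
    filter_alignment,
    prune_cluster,
)

from conftest import mutate, random_seq


class TestAlignCluster:
    def test_identical_sequences_align_without_gaps(self, rng):
        seq = random_seq(rng, 150)
        aln = align_cluster([seq, seq])
        assert aln.rows == [seq, seq]
        assert aln.overlap_len == 150
        assert aln.mean_identity == 100.0

    def test_three_bp_indel_gives_one_gap_run(self, rng):
        a = random_seq(rng, 60)
        b = a[:30] + a[33:]  # one internal codon-sized deletion
        aln = align_cluster([a, b])
        assert len(aln.rows[0]) == 60
        assert aln.rows[0] == a
        assert aln.rows[1].count("-") == 3
        gap_start = aln.rows[1].index("-")
        assert aln.rows[1][gap_start : gap_start + 3] == "---"

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            align_cluster(["ACGTACGT"])

    def test_pairwise_matches_optimal_score_on_toys(self, rng):
        # exhaustive-search oracle over all alignments of short sequences
        # (affine gaps, free end gaps; state: 0 = diagonal, 1/2 = in-gap)
        def best_score(a, b, match=2, mismatch=-2, open_=-5, extend=-1):
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def rec(i, j, state):
                if i == len(a) or j == len(b):
                    return 0.0  # free end gaps
                sub = rec(i + 1, j + 1, 0) + (
                    match if a[i] == b[j] else mismatch
                )
                interior_a = 0 < j < len(b)
                interior_b = 0 < i < len(a)
                ga = rec(i + 1, j, 1) + (
                    (extend if state == 1 else open_) if interior_a else 0.0
                )
                gb = rec(i, j + 1, 2) + (
                    (extend if state == 2 else open_) if interior_b else 0.0
                )
                return max(sub, ga, gb)

            return rec(0, 0, 0)

        def score_rows(r1, r2, match=2, mismatch=-2, open_=-5, extend=-1):
            total = 0.0
            cols = list(zip(r1, r2))
            start, end = 0, len(cols)
            while start < end and "-" in cols[start]:
                start += 1
            while end > start and "-" in cols[end - 1]:
                end -= 1
            in_gap = None
            for x, y in cols[start:end]:
                if "-" in (x, y):
                    which = 0 if x == "-" else 1
                    total += extend if in_gap == which else open_
                    in_gap = which
                else:
                    in_gap = None
                    total += match if x == y else mismatch
            return total

        for _ in range(10):
            a = random_seq(rng, int(rng.integers(8, 20)))
            b = mutate(a, [2])[: int(rng.integers(6, len(a)))]
            aln = align_cluster([a, b])
            got = score_rows(aln.rows[0], aln.rows[1])
            assert got == pytest.approx(best_score(a, b))

    def test_three_sequences_share_alignment_length(self, rng):
        base = random_seq(rng, 200)
        seqs = [base, mutate(base, [50]), base[10:190]]
        aln = align_cluster(seqs)
        assert len({len(r) for r in aln.rows}) == 1
        assert aln.overlap_len >= 170

    def test_missing_external_binary_is_explicit(self):
        with pytest.raises(RuntimeError, match="no-such-aligner"):
            align_cluster(
                ["ACGTACGTACGT", "ACGTACGTACGT"],
                engine="external",
                external_cmd="no-such-aligner {input} {output}",
            )


def _fabricate(rows):
    return ClusterAlignment(
        cluster_id="t", ids=[f"s{i}" for i in range(len(rows))],
        species=[""] * len(rows), rows=rows,
    )


class TestFilterAlignment:
    def test_good_alignment_passes(self, rng):
        seq = random_seq(rng, 250)
        aln = _fabricate([seq, mutate(seq, list(range(0, 250, 13)))])
        ok, reason = filter_alignment(aln)
        assert ok and reason == ""

    def test_short_overlap_fails_on_length(self, rng):
        seq = random_seq(rng, 99)
        aln = _fabricate([seq, seq])
        ok, reason = filter_alignment(aln)
        assert not ok and reason.startswith("length")

    def test_low_identity_fails_on_identity(self, rng):
        seq = random_seq(rng, 1000)
        aln = _fabricate([seq, mutate(seq, list(range(251)))])
        assert aln.mean_identity == pytest.approx(74.9)
        ok, reason = filter_alignment(aln)
        assert not ok and reason.startswith("identity")

    def test_boundaries_are_inclusive(self, rng):
        seq = random_seq(rng, 100)
        aln = _fabricate([seq, mutate(seq, list(range(25)))])
        assert aln.overlap_len == 100
        assert aln.mean_identity == pytest.approx(75.0)
        ok, _ = filter_alignment(aln)
        assert ok


class TestPruneCluster:
    def _aln(self, rng):
        poly = random_seq(rng, 300)
        near = mutate(poly, [10, 50])  # ~99% identical paralog
        far = mutate(poly, list(range(0, 300, 5)))  # ~80% paralog
        ps = mutate(poly, [20, 60, 100])
        pt = mutate(poly, [30, 70, 110, 150])
        og = mutate(poly, list(range(0, 300, 12)))
        return ClusterAlignment(
            cluster_id="c",
            ids=["A1", "Bnear", "Bfar", "Bthird", "C1", "O1"],
            species=["polyploid", "parent_s", "parent_s", "parent_s",
                     "parent_t", "outgroup"],
            rows=[poly, near, far, ps, pt, og],
        )

    def test_keeps_best_scoring_parent(self, rng):
        pruned, reason = prune_cluster(self._aln(rng))
        assert pruned is not None
        kept_s = [i for i, sp in zip(pruned.ids, pruned.species)
                  if sp == "parent_s"]
        assert kept_s == ["Bnear"]

    def test_one_sequence_per_species_unchanged(self, rng):
        seq = random_seq(rng, 200)
        aln = ClusterAlignment(
            cluster_id="c", ids=["a", "b", "c", "o"],
            species=["polyploid", "parent_s", "parent_t", "outgroup"],
            rows=[seq, mutate(seq, [5]), mutate(seq, [9]), mutate(seq, [3])],
        )
        pruned, _ = prune_cluster(aln)
        assert pruned.ids == ["a", "b", "c", "o"]

    def test_missing_outgroup_discards_cluster(self, rng):
        seq = random_seq(rng, 200)
        aln = ClusterAlignment(
            cluster_id="c", ids=["a", "b", "c"],
            species=["polyploid", "parent_s", "parent_t"],
            rows=[seq, seq, seq],
        )
        pruned, reason = prune_cluster(aln)
        assert pruned is None
        assert "outgroup" in reason

    def test_never_removes_polyploid_below_cap(self, rng):
        seq = random_seq(rng, 200)
        aln = ClusterAlignment(
            cluster_id="c", ids=["a1", "a2", "b", "c", "o"],
            species=["polyploid", "polyploid", "parent_s", "parent_t",
                     "outgroup"],
            rows=[seq, mutate(seq, [8]), seq, seq, seq],
        )
        pruned, _ = prune_cluster(aln)
        assert {"a1", "a2"} <= set(pruned.ids)


class TestAttachOutgroup:
    def test_exact_copy_found(self, rng):
        seq = random_seq(rng, 400)
        hit = attach_outgroup(seq, [("og1", seq), ("og2", random_seq(rng, 400))])
        assert hit is not None
        assert hit[0] == "og1" and hit[3] == 100.0

    def test_short_overlap_rejected(self, rng):
        # best hit spans only 95 bp: fails the "more than 100 bp" rule
        seq = random_seq(rng, 300)
        og = random_seq(rng, 100) + seq[100:195] + random_seq(rng, 100)
        assert attach_outgroup(seq, [("og", og)]) is None

    def test_low_identity_rejected(self, rng):
        seq = random_seq(rng, 300)
        diverged = mutate(seq, list(range(0, 300, 3)))  # 2/3 identity
        assert attach_outgroup(seq, [("og", diverged)]) is None

    def test_identity_boundary_70_passes(self, rng):
        seq = random_seq(rng, 400)
        # ~85% identity homolog comfortably above the 70% cutoff
        diverged = mutate(seq, list(range(3, 395, 7)))
        hit = attach_outgroup(seq, [("og", diverged)])
        assert hit is not None and hit[3] >= 70.0

    def test_empty_outgroup_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            attach_outgroup("ACGT" * 50, [])
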