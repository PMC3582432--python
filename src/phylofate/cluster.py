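"""Identity-threshold clustering, consensus contigs, and collapse detection.

This replaces a full overlap-graph EST assembler with the threshold logic the
analysis actually depends on: reads (or contigs) are joined by single-linkage
over the predicate "best local alignment covers >= min_overlap bp at an
identity above the threshold", consensus sequences are built by star
alignment to the longest member, and homeolog collapse in the polyploid
assembly is detected from cross-species pileups on the polyploid consensus
(a full-outer-join of per-species SNP calls).

Identity is percent matching columns over all aligned columns, counting
internal gap columns as mismatches.  A pair merges when its identity strictly
exceeds the threshold, so two sequence groups differing at exactly 3 sites
per 100 bp merge in a 95% assembly and separate in a 97% assembly.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import zlib
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "Contig",
    "GeneCluster",
    "KmerIndex",
    "pairwise_overlap",
    "cluster_at_identity",
    "identity_sweep",
    "build_consensus",
    "species_assembly",
    "split_polymorphic_contig",
    "detect_collapse",
    "cross_species_clusters",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _alignment_stats(aln, a: str, b: str) -> tuple[int, int]:
    """(aligned columns incl. internal gaps, matching columns)."""
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0, 0
    arr_a, arr_b = _to_array(a), _to_array(b)
    matches = 0
    seg = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        matches += int(np.count_nonzero(arr_a[a0:a1] == arr_b[b0:b1]))
        seg += a1 - a0
    gaps = 0
    for k in range(1, len(blocks_a)):
        gaps += blocks_a[k][0] - blocks_a[k - 1][1]
        gaps += blocks_b[k][0] - blocks_b[k - 1][1]
    return seg + gaps, matches


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _seed_offset(a: str, b: str, k: int = 12) -> int | None:
    """Dominant ungapped offset (a_pos - b_pos) from shared k-mers."""
    if len(a) < k or len(b) < k:
        return None
    pos_a: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        hits = pos_a.setdefault(a[i : i + k], [])
        if len(hits) < 8:
            hits.append(i)
    votes: Counter = Counter()
    for j in range(len(b) - k + 1):
        for i in pos_a.get(b[j : j + k], ()):
            votes[i - j] += 1
    if not votes:
        return None
    return max(votes.items(), key=lambda kv: (kv[1], -abs(kv[0]), kv[0]))[0]


def _overlap_from_cigar(cigar: str) -> tuple[int, int]:
    """(aligned columns, matches) with terminal non-match runs trimmed."""
    ops = list(_cigar_ops(cigar))
    while ops and ops[0][1] != "=":
        ops.pop(0)
    while ops and ops[-1][1] != "=":
        ops.pop()
    columns = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    return columns, matches


def _dp_overlap(a: str, b: str) -> tuple[int, float]:
    """Full Smith-Waterman fallback when no seed exists."""
    alns = _ALIGNER.align(a, b)
    if alns.score <= 0:
        return 0, 0.0
    try:
        aln = alns[0]
    except IndexError:
        return 0, 0.0
    columns, matches = _alignment_stats(aln, a, b)
    if columns == 0:
        return 0, 0.0
    return columns, 100.0 * matches / columns


def pairwise_overlap(a: str, b: str, min_overlap: int = 40) -> tuple[int, float]:
    """Best overlap-alignment length (bp) and percent identity.

    The dominant shared-k-mer offset defines the overlap window, which is
    then aligned end-to-end (edit-distance alignment) with terminal
    non-matching columns trimmed; internal gap columns count as mismatches.
    When no seed exists the full local-alignment search is used.  Returns
    ``(0, 0.0)`` when no alignment of at least ``min_overlap`` columns
    exists.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return len(a), 100.0
    offset = _seed_offset(a, b)
    if offset is None:
        columns, identity = _dp_overlap(a, b)
    else:
        a0, a1 = max(0, offset), min(len(a), len(b) + offset)
        if a1 - a0 < 1:
            return 0, 0.0
        res = edlib.align(b[a0 - offset : a1 - offset], a[a0:a1],
                          mode="NW", task="path")
        columns, matches = _overlap_from_cigar(res["cigar"])
        identity = 100.0 * matches / columns if columns else 0.0
    if columns < min_overlap:
        return 0, 0.0
    return columns, identity


def _merges(a: str, b: str, threshold: float, min_overlap: int) -> bool:
    overlap, identity = pairwise_overlap(a, b, min_overlap)
    return overlap >= min_overlap and identity > threshold


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


_KMER_FRACTION = 8  # FracMinHash sampling: keep ~1/8 of k-mers


def _sampled_kmers(seq: str, k: int) -> set[str]:
    limit = 2**32 // _KMER_FRACTION
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if zlib.crc32(kmer.encode()) < limit:
            out.add(kmer)
    return out


def _candidate_pairs(seqs: list[str], k: int = 14, max_bucket: int = 200) -> list:
    buckets: dict[str, list[int]] = defaultdict(list)
    for idx, seq in enumerate(seqs):
        for kmer in _sampled_kmers(seq, k):
            buckets[kmer].append(idx)
    shared: Counter = Counter()
    for members in buckets.values():
        if len(members) > max_bucket:
            members = members[:max_bucket]
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                shared[(members[x], members[y])] += 1
    # strongest-sharing pairs first, so likely merges come early and the
    # union-find can skip the rest of each component
    return [p for p, _ in sorted(shared.items(), key=lambda kv: (-kv[1], kv[0]))]


def _all_pairs(n: int) -> list:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]

#: above this many sequences an exact all-pairs comparison is replaced by a
#: shared-k-mer candidate prefilter (heuristic; exact below the limit)
EXACT_LIMIT = 60


def cluster_at_identity(
    seqs,
    threshold: float,
    min_overlap: int = 40,
    ids=None,
) -> list[list]:
    """Single-linkage clusters under the overlap/identity merge predicate.

    Returns clusters as lists of ids (or indices when ``ids`` is None),
    ordered by smallest member; the partition is independent of input order.
    """
    if not 50 <= threshold <= 100:
        raise ValueError("threshold must be in [50, 100]")
    seqs = list(seqs)
    n = len(seqs)
    uf = _UnionFind(n)
    pairs = _all_pairs(n) if n <= EXACT_LIMIT else _candidate_pairs(seqs)
    for i, j in pairs:
        if uf.find(i) == uf.find(j):
            continue
        if _merges(seqs[i], seqs[j], threshold, min_overlap):
            uf.union(i, j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[uf.find(i)].append(i)
    clusters = [sorted(members) for _, members in sorted(groups.items())]
    if ids is not None:
        ids = list(ids)
        clusters = [[ids[i] for i in cl] for cl in clusters]
    return clusters


def identity_sweep(seqs, thresholds, min_overlap: int = 40) -> dict:
    """Cluster counts per identity threshold (the assembly-parameter sweep).

    Counts are non-decreasing in the threshold for fixed ``min_overlap``.
    """
    seqs = list(seqs)
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    n = len(seqs)
    pairs = _all_pairs(n) if n <= EXACT_LIMIT else _candidate_pairs(seqs)
    stats = {}
    for i, j in pairs:
        stats[(i, j)] = pairwise_overlap(seqs[i], seqs[j], min_overlap)
    counts = {}
    for t in thresholds:
        uf = _UnionFind(n)
        for (i, j), (overlap, identity) in stats.items():
            if overlap >= min_overlap and identity > t:
                uf.union(i, j)
        counts[t] = len({uf.find(i) for i in range(n)})
    return counts


# ---------------------------------------------------------------------------
# consensus contigs


@dataclass
class Contig:
    """Consensus sequence of one read cluster in one species."""

    id: str
    species: str
    consensus: str
    members: list
    depth_profile: list
    #: read id -> (start position on consensus, bases aligned per position,
    #: '-' where the read skips a consensus position; insertions dropped)
    placements: dict = field(default_factory=dict, repr=False)


def _project_member(
    ref: str, seq: str, max_divergence: float = 0.35
) -> list[tuple[int, str]] | None:
    """Positions of ``seq`` bases in reference coordinates.

    The dominant shared-k-mer offset defines the overlap, which is aligned
    end-to-end; flanks overhanging the overlap are placed by ungapped
    extension (coordinates may run past either reference end) and
    insertions relative to the reference are dropped.  Members without a
    seed or more than ``max_divergence`` diverged over the overlap are left
    unplaced.
    """
    offset = _seed_offset(ref, seq)
    if offset is None:
        return _project_member_dp(ref, seq)
    r0, r1 = max(0, offset), min(len(ref), len(seq) + offset)
    if r1 - r0 < 1:
        return None
    q0, q1 = r0 - offset, r1 - offset
    res = edlib.align(seq[q0:q1], ref[r0:r1], mode="NW", task="path")
    if res["editDistance"] > max_divergence * (q1 - q0):
        return None
    placed: list[tuple[int, str]] = []
    for k in range(q0):  # leading overhang, ungapped extension
        placed.append((r0 - q0 + k, seq[k]))
    qi, ti = q0, r0
    for n, op in _cigar_ops(res["cigar"]):
        if op in "=XM":
            for k in range(n):
                placed.append((ti + k, seq[qi + k]))
            qi += n
            ti += n
        elif op == "I":  # insertion in member: no reference column
            qi += n
        elif op == "D":
            ti += n
    for k in range(len(seq) - q1):  # trailing overhang
        placed.append((r1 + k, seq[q1 + k]))
    return placed


def _project_member_dp(
    ref: str, seq: str, max_divergence: float = 0.35
) -> list[tuple[int, str]] | None:
    """Local-alignment fallback projection for short or seedless members.

    The local alignment must cover at least min(40, len(seq)) columns at
    <= ``max_divergence`` mismatches, so unrelated members stay unplaced.
    """
    alns = _ALIGNER.align(ref, seq)
    if alns.score <= 0:
        return None
    try:
        aln = alns[0]
    except IndexError:
        return None
    columns, matches = _alignment_stats(aln, ref, seq)
    if columns < min(40, len(seq)):
        return None
    if matches < (1 - max_divergence) * columns:
        return None
    blocks_r, blocks_q = aln.aligned
    if len(blocks_r) == 0:
        return None
    placed: list[tuple[int, str]] = []
    r0, q0 = blocks_r[0][0], blocks_q[0][0]
    for k in range(q0):  # leading flank, ungapped extension
        placed.append((r0 - q0 + k, seq[k]))
    for (rs, re), (qs, qe) in zip(blocks_r, blocks_q):
        for k in range(re - rs):
            placed.append((rs + k, seq[qs + k]))
    r1, q1 = blocks_r[-1][1], blocks_q[-1][1]
    for k in range(len(seq) - q1):  # trailing flank
        placed.append((r1 + k, seq[q1 + k]))
    return placed


def _majority_string(columns: dict) -> tuple[str, int]:
    """Majority base over the full covered coordinate span ('N' at holes)."""
    lo, hi = min(columns), max(columns)
    out = []
    for pos in range(lo, hi + 1):
        counter = columns.get(pos)
        if not counter:
            out.append("N")
        else:
            out.append(min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0])
    return "".join(out), lo


def build_consensus(members, contig_id: str = "contig", species: str = "") -> Contig:
    """Star-align cluster members to the longest one; per-column majority base.

    Members that do not overlap the longest read directly are attached in
    later rounds against the growing consensus, so a chain of overlapping
    reads assembles end to end.  Ties between bases are broken in A<C<G<T
    order; if coverage stays discontiguous the longest covered stretch is
    kept.
    """
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    ref_id, ref = max(members, key=lambda m: (len(m[1]), m[0]))
    columns: dict[int, Counter] = defaultdict(Counter)
    read_pos: dict[str, list[tuple[int, str]]] = {}
    read_pos[ref_id] = [(k, base) for k, base in enumerate(ref)]
    for pos, base in read_pos[ref_id]:
        columns[pos][base] += 1
    remaining = [(mid, seq) for mid, seq in members if mid != ref_id]
    target, target_lo = ref, 0
    while remaining:
        progress = False
        still = []
        for mid, seq in remaining:
            placed = _project_member(target, seq)
            if placed is None:
                still.append((mid, seq))
                continue
            placed = [(pos + target_lo, base) for pos, base in placed]
            read_pos[mid] = placed
            for pos, base in placed:
                columns[pos][base] += 1
            progress = True
        remaining = still
        if not progress or not remaining:
            break
        target, target_lo = _majority_string(columns)
    coords = sorted(columns)
    runs: list[list[int]] = [[coords[0], coords[0]]]
    for c in coords[1:]:
        if c == runs[-1][1] + 1:
            runs[-1][1] = c
        else:
            runs.append([c, c])
    lo, hi = max(runs, key=lambda r: r[1] - r[0])
    consensus = []
    depth = []
    for pos in range(lo, hi + 1):
        counter = columns[pos]
        best = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        consensus.append(best)
        depth.append(sum(counter.values()))
    placements = {}
    kept_members = []
    for mid, _ in members:
        placed = read_pos.get(mid)
        if placed is None:
            continue
        inside = [(p, b) for p, b in placed if lo <= p <= hi]
        if not inside:
            continue
        start = min(p for p, _ in inside)
        end = max(p for p, _ in inside)
        bases = ["-"] * (end - start + 1)
        for p, b in inside:
            bases[p - start] = b
        placements[mid] = (start - lo, "".join(bases))
        kept_members.append(mid)
    return Contig(
        id=contig_id,
        species=species,
        consensus="".join(consensus),
        members=kept_members,
        depth_profile=depth,
        placements=placements,
    )


def species_assembly(
    reads,
    species: str,
    threshold: float = 97.0,
    min_overlap: int = 40,
    min_contig_len: int = 40,
    min_contig_reads: int = 3,
) -> tuple[list[Contig], dict]:
    """Cluster one species' reads and build consensus contigs.

    Contigs with a consensus shorter than ``min_contig_len`` or built from
    fewer than ``min_contig_reads`` reads are dropped (sparse fragments give
    unreliable consensus and distance estimates).  Returns the contigs and a
    read id -> contig id membership map.
    """
    ids = [r.id for r in reads]
    seqs = [r.sequence for r in reads]
    clusters = cluster_at_identity(seqs, threshold, min_overlap)
    contigs = []
    membership: dict[str, str] = {}
    n = 0
    for cl in clusters:
        if len(cl) < min_contig_reads:
            continue
        contig = build_consensus(
            [(ids[i], seqs[i]) for i in cl],
            contig_id=f"{species}_c{n:05d}",
            species=species,
        )
        if len(contig.consensus) < min_contig_len:
            continue
        if len(contig.members) < min_contig_reads:
            continue
        n += 1
        contigs.append(contig)
        for mid in contig.members:
            membership[mid] = contig.id
    return contigs, membership


# ---------------------------------------------------------------------------
# phasing-based split of collapsed polyploid contigs


def _polymorphic_columns(
    contig: Contig, min_minor_count: int = 2, min_minor_freq: float = 0.2
) -> list[int]:
    cols = []
    counts: dict[int, Counter] = defaultdict(Counter)
    for start, bases in contig.placements.values():
        for k, b in enumerate(bases):
            if b != "-":
                counts[start + k][b] += 1
    for pos in sorted(counts):
        ranked = counts[pos].most_common()
        if len(ranked) < 2:
            continue
        depth = sum(c for _, c in ranked)
        minor = ranked[1][1]
        if minor >= min_minor_count and minor / depth >= min_minor_freq:
            cols.append(pos)
    return cols


def split_polymorphic_contig(
    contig: Contig, min_minor_count: int = 2, min_minor_freq: float = 0.2
) -> list[Contig]:
    """Split a polymorphic contig into two phased haplotype contigs.

    Reads are partitioned by their alleles at intra-contig polymorphic
    columns (seeded at the deepest such column, then refined by agreement
    with the two haplotype consensuses).  Returns the original contig when
    there is nothing to phase or one side would hold fewer than two reads.
    """
    cols = _polymorphic_columns(contig, min_minor_count, min_minor_freq)
    if not cols:
        return [contig]
    alleles: dict[str, dict[int, str]] = {}
    for mid, (start, bases) in contig.placements.items():
        row = {}
        for pos in cols:
            k = pos - start
            if 0 <= k < len(bases) and bases[k] != "-":
                row[pos] = bases[k]
        alleles[mid] = row
    depth = Counter()
    for row in alleles.values():
        for pos in row:
            depth[pos] += 1
    seed = min(cols, key=lambda p: (-depth[p], p))
    seed_counts = Counter(row[seed] for row in alleles.values() if seed in row)
    ranked = seed_counts.most_common()
    if len(ranked) < 2:
        return [contig]
    a1, a2 = ranked[0][0], ranked[1][0]
    assign: dict[str, int] = {}
    for mid, row in alleles.items():
        if row.get(seed) == a1:
            assign[mid] = 0
        elif row.get(seed) == a2:
            assign[mid] = 1
    for _ in range(3):
        hap_base: list[dict[int, str]] = [{}, {}]
        for h in (0, 1):
            for pos in cols:
                votes = Counter(
                    alleles[mid][pos]
                    for mid, hh in assign.items()
                    if hh == h and pos in alleles[mid]
                )
                if votes:
                    hap_base[h][pos] = min(
                        votes.items(), key=lambda kv: (-kv[1], kv[0])
                    )[0]
        new_assign: dict[str, int] = {}
        for mid, row in alleles.items():
            scores = [0, 0]
            for h in (0, 1):
                for pos, b in row.items():
                    if hap_base[h].get(pos) == b:
                        scores[h] += 1
            if scores[0] > scores[1]:
                new_assign[mid] = 0
            elif scores[1] > scores[0]:
                new_assign[mid] = 1
            elif mid in assign:
                new_assign[mid] = assign[mid]
        assign = new_assign
    sizes = Counter(assign.values())
    n0, n1 = sizes.get(0, 0), sizes.get(1, 0)
    bigger = 0 if n0 >= n1 else 1
    groups: dict[int, list[str]] = {0: [], 1: []}
    for mid in contig.members:
        groups[assign.get(mid, bigger)].append(mid)
    if min(len(groups[0]), len(groups[1])) < 2:
        return [contig]
    out = []
    for h, suffix in ((0, "a"), (1, "b")):
        sub = _contig_from_placements(
            f"{contig.id}{suffix}",
            contig.species,
            {mid: contig.placements[mid] for mid in groups[h]},
        )
        if sub is not None:
            out.append(sub)
    return out if len(out) == 2 else [contig]


def _contig_from_placements(contig_id, species, placements) -> Contig | None:
    columns: dict[int, Counter] = defaultdict(Counter)
    for start, bases in placements.values():
        for k, b in enumerate(bases):
            if b != "-":
                columns[start + k][b] += 1
    if not columns:
        return None
    coords = sorted(columns)
    runs: list[list[int]] = [[coords[0], coords[0]]]
    for c in coords[1:]:
        if c == runs[-1][1] + 1:
            runs[-1][1] = c
        else:
            runs.append([c, c])
    lo, hi = max(runs, key=lambda r: r[1] - r[0])
    consensus = []
    depth = []
    for pos in range(lo, hi + 1):
        counter = columns[pos]
        best = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        consensus.append(best)
        depth.append(sum(counter.values()))
    new_placements = {}
    members = []
    for mid, (start, bases) in placements.items():
        inside = [
            (start + k, b)
            for k, b in enumerate(bases)
            if b != "-" and lo <= start + k <= hi
        ]
        if not inside:
            continue
        s = min(p for p, _ in inside)
        e = max(p for p, _ in inside)
        row = ["-"] * (e - s + 1)
        for p, b in inside:
            row[p - s] = b
        new_placements[mid] = (s - lo, "".join(row))
        members.append(mid)
    return Contig(
        id=contig_id,
        species=species,
        consensus="".join(consensus),
        members=members,
        depth_profile=depth,
        placements=new_placements,
    )


# ---------------------------------------------------------------------------
# read mapping and collapse detection


class KmerIndex:
    """Shared-k-mer candidate lookup over a set of target sequences."""

    def __init__(self, seqs, k: int = 12):
        self.k = k
        self.index: dict[str, set[int]] = defaultdict(set)
        self.n = len(seqs)
        for idx, seq in enumerate(seqs):
            for i in range(0, len(seq) - k + 1):
                self.index[seq[i : i + k]].add(idx)

    def candidates(self, query: str) -> list[int]:
        hits: set[int] = set()
        k = self.k
        for i in range(0, len(query) - k + 1, k):  # non-overlapping windows
            hits |= self.index.get(query[i : i + k], set())
        return sorted(hits)


def map_read(read_seq: str, consensus: str, min_identity: float = 90.0):
    """Place a read on a consensus with edlib; returns [(pos, base), ...] or None."""
    res = edlib.align(read_seq, consensus, mode="HW", task="path")
    dist = res["editDistance"]
    if dist < 0:
        return None
    identity = 100.0 * (1 - dist / max(len(read_seq), 1))
    if identity < min_identity:
        return None
    start = res["locations"][0][0]
    placed = []
    qi, ti = 0, start
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            for k in range(n):
                placed.append((ti + k, read_seq[qi + k]))
            qi += n
            ti += n
        elif ch == "I":  # insertion in read; no consensus position
            qi += n
        elif ch == "D":  # read skips consensus positions
            ti += n
    return placed


def detect_collapse(
    polyploid_contigs,
    reads_by_species: dict,
    min_depth: int = 4,
    min_af: float = 0.8,
    map_min_identity: float = 90.0,
    parent_species=("parent_s", "parent_t"),
    polyploid_species: str = "polyploid",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-species SNP concordance on the polyploid assembly.

    Each species' reads are mapped to their best-matching polyploid contig and
    piled up.  A position is an inter-parent SNP when both parents have
    coverage >= ``min_depth`` and different major alleles, each at frequency
    >= ``min_af``.  Per-species calls are joined across species with
    full-outer-join semantics (positions present in any species retained,
    absent species marked "no_coverage").

    Returns ``(snp_table, collapse_report)``: one row per variant position
    and one row per contig with its distinguishability class.
    """
    contigs = list(polyploid_contigs)
    species_list = [polyploid_species, *parent_species]
    index = KmerIndex([c.consensus for c in contigs], k=12)
    pileups = {
        c.id: {sp: defaultdict(Counter) for sp in species_list} for c in contigs
    }
    for sp in species_list:
        for read in reads_by_species.get(sp, []):
            cands = index.candidates(read.sequence)
            best = None
            for ci in cands:
                res = edlib.align(read.sequence, contigs[ci].consensus, mode="HW")
                d = res["editDistance"]
                if d >= 0 and (best is None or d < best[1]):
                    best = (ci, d)
            if best is None:
                continue
            ci, dist = best
            if 100.0 * (1 - dist / max(len(read.sequence), 1)) < map_min_identity:
                continue
            placed = map_read(
                read.sequence, contigs[ci].consensus, map_min_identity
            )
            if placed is None:
                continue
            pile = pileups[contigs[ci].id][sp]
            for pos, base in placed:
                pile[pos][base] += 1

    snp_rows = []
    report_rows = []
    for contig in contigs:
        pile = pileups[contig.id]
        n_snps = 0
        polymorphic = False
        positions = sorted(set().union(*(pile[sp].keys() for sp in species_list)))
        for pos in positions:
            if pos < 0 or pos >= len(contig.consensus):
                continue
            ref_base = contig.consensus[pos]
            calls = {}
            for sp in species_list:
                counter = pile[sp].get(pos)
                depth = sum(counter.values()) if counter else 0
                if not counter or depth < min_depth:
                    calls[sp] = ("no_coverage", depth, 0.0, 0)
                    continue
                (major, cnt), *rest = sorted(
                    counter.items(), key=lambda kv: (-kv[1], kv[0])
                )
                freq = cnt / depth
                minor = rest[0][1] if rest else 0
                calls[sp] = (major, depth, freq, minor)
            s_call, t_call = (calls[sp] for sp in parent_species)
            inter_parent = (
                s_call[0] != "no_coverage"
                and t_call[0] != "no_coverage"
                and s_call[0] != t_call[0]
                and s_call[2] >= min_af
                and t_call[2] >= min_af
            )
            p_call = calls[polyploid_species]
            poly_here = (
                p_call[0] != "no_coverage"
                and p_call[3] >= 2
                and p_call[3] / p_call[1] >= 1 - min_af
            )
            if inter_parent:
                n_snps += 1
            if poly_here:
                polymorphic = True
            variant = any(
                calls[sp][0] not in ("no_coverage", ref_base) for sp in species_list
            )
            if inter_parent or poly_here or variant:
                row = {
                    "contig": contig.id,
                    "position": pos,
                    "ref_base": ref_base,
                    "interparent_snp": inter_parent,
                    "polyploid_polymorphic": poly_here,
                }
                for sp in species_list:
                    row[f"call_{sp}"] = calls[sp][0]
                    row[f"depth_{sp}"] = calls[sp][1]
                snp_rows.append(row)
        report_rows.append(
            {
                "contig": contig.id,
                "class": (
                    "parent_distinguishable" if n_snps >= 1 else "non_distinguishable"
                ),
                "n_interparent_snps": n_snps,
                "polyploid_polymorphic": polymorphic,
            }
        )
    snp_cols = [
        "contig", "position", "ref_base", "interparent_snp",
        "polyploid_polymorphic",
    ] + [f"{w}_{sp}" for sp in species_list for w in ("call", "depth")]
    snps = pd.DataFrame(snp_rows, columns=snp_cols if not snp_rows else None)
    report = pd.DataFrame(
        report_rows,
        columns=["contig", "class", "n_interparent_snps", "polyploid_polymorphic"],
    )
    return snps, report


# ---------------------------------------------------------------------------
# cross-species gene clusters


@dataclass
class GeneCluster:
    """Cross-species group of contigs for (putatively) one gene."""

    id: str
    contigs: list

    @property
    def species_present(self) -> set:
        return {c.species for c in self.contigs}

    def by_species(self, species: str) -> list:
        return [c for c in self.contigs if c.species == species]


def cross_species_clusters(
    contigs_by_species: dict, threshold: float = 95.0, min_overlap: int = 40
) -> list[GeneCluster]:
    """Join the per-species assemblies into gene clusters at lower stringency."""
    contigs = [c for sp in sorted(contigs_by_species) for c in contigs_by_species[sp]]
    seqs = [c.consensus for c in contigs]
    groups = cluster_at_identity(seqs, threshold, min_overlap)
    clusters = []
    for n, group in enumerate(groups):
        clusters.append(
            GeneCluster(id=f"cl{n:05d}", contigs=[contigs[i] for i in group])
        )
    return clusters
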