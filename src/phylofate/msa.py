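"""Per-cluster multiple alignment, quality filters, pruning, outgroup attach.

The builtin aligner is a progressive aligner: a UPGMA guide tree is built on
pairwise k-mer distances and profiles are merged by globally aligning their
majority-consensus strings (configurable match/mismatch/affine-gap scores;
end gaps are free).
An external aligner (ClustalW/MAFFT/MUSCLE style) can be substituted through
a command template.

Filters follow the pipeline's cited defaults: an alignment passes when its
globally covered overlap is >= 100 bp and its mean pairwise identity is
>= 75%; an outgroup homolog must align over more than 100 bp at >= 70%
identity.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .cluster import KmerIndex, pairwise_overlap

__all__ = [
    "ClusterAlignment",
    "align_cluster",
    "filter_alignment",
    "prune_cluster",
    "attach_outgroup",
]


@dataclass
class ClusterAlignment:
    """Gapped, equal-length rows plus the filter statistics."""

    cluster_id: str
    ids: list
    species: list
    rows: list
    overlap_len: int = 0
    mean_identity: float = 0.0
    passed: bool = False
    fail_reason: str = ""

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        self.overlap_len, self.mean_identity = _alignment_quality(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset(self, keep_idx) -> "ClusterAlignment":
        rows = [self.rows[i] for i in keep_idx]
        arr = np.array([list(r) for r in rows])
        non_gap = (arr != "-").any(axis=0)
        rows = ["".join(row[non_gap]) for row in arr]
        return ClusterAlignment(
            cluster_id=self.cluster_id,
            ids=[self.ids[i] for i in keep_idx],
            species=[self.species[i] for i in keep_idx],
            rows=rows,
        )


def _alignment_quality(rows) -> tuple[int, float]:
    """(columns covered by every row, mean pairwise identity %)."""
    if len(rows) < 2:
        return (len(rows[0]) if rows else 0), 100.0
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    gap = ord("-")
    covered_all = int(((arr != gap).all(axis=0)).sum())
    idents = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            both = (arr[i] != gap) & (arr[j] != gap)
            n = int(both.sum())
            if n == 0:
                idents.append(0.0)
                continue
            matches = int((arr[i][both] == arr[j][both]).sum())
            idents.append(100.0 * matches / n)
    return covered_all, float(np.mean(idents))


# ---------------------------------------------------------------------------
# builtin progressive aligner


def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _pair_align(a: str, b: str, match, mismatch, gap_open, gap_extend):
    # end gaps are free: cluster members are transcript fragments that may
    # cover different regions, so overhangs must not be penalized; affine
    # gaps keep each indel in one contiguous run
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    return aln


_PROFILE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _profile_consensus(rows) -> str:
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    counts = np.stack([(arr == b).sum(axis=0) for b in _PROFILE_BASES])
    best = _PROFILE_BASES[np.argmax(counts, axis=0)]  # ties: A<C<G<T
    best = np.where(counts.max(axis=0) == 0, ord("N"), best)
    return best.astype(np.uint8).tobytes().decode()


def _merge_profiles(rows_a, rows_b, match, mismatch, gap_open, gap_extend):
    ca, cb = _profile_consensus(rows_a), _profile_consensus(rows_b)
    aln = _pair_align(ca, cb, match, mismatch, gap_open, gap_extend)
    blocks_a, blocks_b = aln.aligned
    cols_a: list[int] = []
    cols_b: list[int] = []
    pa = pb = 0

    def emit(na: int, nb: int):
        nonlocal pa, pb
        n = max(na, nb)
        for k in range(n):
            cols_a.append(pa + k if k < na else -1)
            cols_b.append(pb + k if k < nb else -1)
        pa += na
        pb += nb

    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        emit(as_ - pa, bs - pb)  # gap region before this block
        emit(ae - as_, be - bs)
    emit(len(ca) - pa, len(cb) - pb)

    def take(rows, cols):
        idx = np.asarray(cols)
        out = []
        for row in rows:
            arr = np.frombuffer(row.encode(), dtype=np.uint8)
            merged = np.where(idx >= 0, arr[np.clip(idx, 0, None)], ord("-"))
            out.append(merged.astype(np.uint8).tobytes().decode())
        return out

    return take(rows_a, cols_a) + take(rows_b, cols_b)


def _builtin_msa(seqs, match, mismatch, gap_open, gap_extend):
    if len(seqs) == 2:
        aln = _pair_align(seqs[0], seqs[1], match, mismatch, gap_open, gap_extend)
        return [str(aln[0]), str(aln[1])]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(seqs[i], seqs[j])
    guide = to_tree(linkage(squareform(dist, checks=False), method="average"))

    def walk(node):
        if node.is_leaf():
            return [node.id], [seqs[node.id]]
        ids_l, rows_l = walk(node.get_left())
        ids_r, rows_r = walk(node.get_right())
        merged = _merge_profiles(rows_l, rows_r, match, mismatch, gap_open,
                                 gap_extend)
        return ids_l + ids_r, merged

    order, rows = walk(guide)
    unscrambled = [None] * n
    for pos, idx in enumerate(order):
        unscrambled[idx] = rows[pos]
    return unscrambled


def _external_msa(seqs, ids, command_template: str):
    binary = command_template.split()[0]
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"external aligner '{binary}' not found on PATH "
            f"(command template: {command_template!r})"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        with open(infile, "w") as fh:
            for sid, seq in zip(ids, seqs):
                fh.write(f">{sid}\n{seq}\n")
        cmd = command_template.format(input=infile, output=outfile)
        result = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if result.returncode != 0:
            raise RuntimeError(f"external aligner failed: {result.stderr[:500]}")
        if outfile.exists():
            records = list(SeqIO.parse(str(outfile), "fasta"))
        else:  # aligners like mafft write to stdout
            from io import StringIO

            records = list(SeqIO.parse(StringIO(result.stdout), "fasta"))
        by_id = {r.id: str(r.seq).upper() for r in records}
        return [by_id[sid] for sid in ids]


def align_cluster(
    seqs,
    ids=None,
    species=None,
    cluster_id: str = "cluster",
    engine: str = "builtin",
    external_cmd: str | None = None,
    match: float = 2,
    mismatch: float = -2,
    gap_open: float = -5,
    gap_extend: float = -1,
) -> ClusterAlignment:
    """Multiple-align a cluster's sequences (>= 2 required)."""
    seqs = [s.upper() for s in seqs]
    if len(seqs) < 2:
        raise ValueError("align_cluster requires at least 2 sequences")
    ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(seqs))]
    species = list(species) if species is not None else [""] * len(seqs)
    if engine == "builtin":
        rows = _builtin_msa(seqs, match, mismatch, gap_open, gap_extend)
    elif engine == "external":
        if not external_cmd:
            raise ValueError("external engine requires a command template")
        rows = _external_msa(seqs, ids, external_cmd)
    else:
        raise ValueError(f"unknown alignment engine {engine!r}")
    return ClusterAlignment(
        cluster_id=cluster_id, ids=ids, species=species, rows=rows
    )


def filter_alignment(
    alignment: ClusterAlignment,
    min_overlap: int = 100,
    min_identity: float = 75.0,
) -> tuple[bool, str]:
    """Pass iff overlap >= min_overlap bp and mean identity >= min_identity %."""
    if alignment.overlap_len < min_overlap:
        alignment.passed = False
        alignment.fail_reason = (
            f"length: overlap {alignment.overlap_len} < {min_overlap}"
        )
    elif alignment.mean_identity < min_identity:
        alignment.passed = False
        alignment.fail_reason = (
            f"identity: {alignment.mean_identity:.1f}% < {min_identity}%"
        )
    else:
        alignment.passed = True
        alignment.fail_reason = ""
    return alignment.passed, alignment.fail_reason


def _row_score(a: str, b: str, match=2, mismatch=-2, gap=-2) -> float:
    score = 0.0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            score += gap
        elif x == y:
            score += match
        else:
            score += mismatch
    return score


def prune_cluster(
    alignment: ClusterAlignment,
    max_per_species: int = 1,
    max_polyploid: int = 2,
    polyploid_species: str = "polyploid",
    required_species=("polyploid", "parent_s", "parent_t", "outgroup"),
) -> tuple[ClusterAlignment | None, str]:
    """Keep the sequences most closely related to the polyploid members.

    For each non-polyploid species, the sequence(s) maximizing the summed
    pairwise alignment score to the polyploid rows are retained (at most
    ``max_per_species``); at most ``max_polyploid`` polyploid rows are kept,
    ranked by summed score to the parental rows.  Clusters missing any
    required species after pruning are discarded with a reason.
    """
    poly_idx = [
        i for i, sp in enumerate(alignment.species) if sp == polyploid_species
    ]
    other_idx = [
        i for i, sp in enumerate(alignment.species) if sp != polyploid_species
    ]
    parent_idx = [
        i
        for i, sp in enumerate(alignment.species)
        if sp in ("parent_s", "parent_t")
    ]
    keep = []
    if len(poly_idx) > max_polyploid:
        ranked = sorted(
            poly_idx,
            key=lambda i: (
                -sum(
                    _row_score(alignment.rows[i], alignment.rows[j])
                    for j in parent_idx
                ),
                alignment.ids[i],
            ),
        )
        keep.extend(ranked[:max_polyploid])
    else:
        keep.extend(poly_idx)
    by_species: dict[str, list[int]] = {}
    for i in other_idx:
        by_species.setdefault(alignment.species[i], []).append(i)
    for sp in sorted(by_species):
        ranked = sorted(
            by_species[sp],
            key=lambda i: (
                -sum(
                    _row_score(alignment.rows[i], alignment.rows[j])
                    for j in poly_idx
                ),
                alignment.ids[i],
            ),
        )
        keep.extend(ranked[:max_per_species])
    keep = sorted(keep)
    pruned = alignment.subset(keep)
    missing = set(required_species) - set(pruned.species)
    if missing:
        return None, f"missing species: {','.join(sorted(missing))}"
    return pruned, ""


def attach_outgroup(
    consensus: str,
    outgroup_seqs,
    min_overlap: int = 100,
    min_identity: float = 70.0,
    index: KmerIndex | None = None,
):
    """Best outgroup homolog passing > min_overlap bp and >= min_identity %.

    ``outgroup_seqs`` is a list of (id, sequence); returns
    ``(id, sequence, overlap, identity)`` or None.  Ties break by overlap
    then lexical id.  An optional prebuilt ``KmerIndex`` over the outgroup
    sequences avoids the all-against-all scan.
    """
    outgroup_seqs = list(outgroup_seqs)
    if not outgroup_seqs:
        raise ValueError("outgroup set is empty")
    if index is not None:
        pool = [outgroup_seqs[i] for i in index.candidates(consensus)]
    else:
        pool = outgroup_seqs
    best = None
    for oid, seq in pool:
        overlap, identity = pairwise_overlap(consensus, seq, min_overlap=1)
        if overlap > min_overlap and identity >= min_identity:
            key = (-overlap * identity, -overlap, oid)
            if best is None or key < best[0]:
                best = (key, (oid, seq, overlap, identity))
    return best[1] if best else None
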