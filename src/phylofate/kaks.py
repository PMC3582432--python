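"""NG86 Ka/Ks estimation with ORF prediction and codon-aware alignment.

Coding regions are predicted as the longest ATG-initiated, stop-free (or
end-truncated) open reading frame over all six frames.  Pairs of CDSs are
aligned at the protein level and the gaps back-threaded as codon triplets;
gapped codon columns are excluded from counting.

Counting follows Nei & Gojobori (1986): each codon position contributes a
synonymous-site fraction equal to its synonymous one-step changes over 3
(changes to stop codons count as nonsynonymous, so S + N = 3 per codon);
sites are averaged over the two sequences.  Codons differing at 2-3
positions average their synonymous/nonsynonymous difference counts over all
minimal substitution pathways with equal weight.  ps = Sd/S and pn = Nd/N
are Jukes-Cantor corrected, K = -(3/4) ln(1 - 4p/3).

omega = Kn/Ks, with the sentinel omega = 99 whenever Ks = 0 (including the
0/0 case of identical sequences); sentinel pairs are flagged ``removed`` and
excluded from selection screens, and omega > 1 flags positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import (
    CODON_TO_AA,
    STOP_CODONS,
    SYN_SITES,
    revcomp,
    translate,
)

__all__ = [
    "CodingRegion",
    "KaKsPair",
    "longest_orf_6frame",
    "codon_align",
    "ng86_kaks",
    "screen_selection",
]

OMEGA_SENTINEL = 99.0


@dataclass
class CodingRegion:
    source_id: str
    frame: int  # +1..+3, -1..-3
    start: int  # 0-based, half-open on the source sequence
    end: int
    cds: str


@dataclass
class KaKsPair:
    id_a: str
    id_b: str
    codons_compared: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    Ks: float | None
    Kn: float | None
    omega: float | None
    removed: bool = False
    positive_selection: bool = False
    valid: bool = True
    reason: str = ""


def longest_orf_6frame(
    sequence: str, source_id: str = "", require_atg: bool = True
) -> CodingRegion | None:
    """Longest ATG-initiated stop-free ORF over all six reading frames.

    The ORF may be truncated by the sequence end.  Ties break by frame order
    +1, +2, +3, -1, -2, -3 then leftmost start.  Returns None when no ORF
    exists (e.g. no ATG in any frame with ``require_atg``).
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    best = None  # (-length, frame_order, start_in_frame, frame, seq_used)
    frames = [(+1, 0), (+2, 1), (+3, 2), (-1, 0), (-2, 1), (-3, 2)]
    for order, (frame, offset) in enumerate(frames):
        seq = sequence if frame > 0 else revcomp(sequence)
        codons = [
            seq[i : i + 3]
            for i in range(offset, len(seq) - 2, 3)
        ]
        start_idx = None
        for ci, codon in enumerate(codons + ["TAA"]):  # sentinel stop at end
            is_stop = codon in STOP_CODONS or ci == len(codons)
            if start_idx is None:
                if (codon == "ATG" or not require_atg) and not is_stop:
                    start_idx = ci
                continue
            if is_stop:
                length = (ci - start_idx) * 3
                cand = (-length, order, start_idx * 3 + offset)
                if best is None or cand < best[:3]:
                    best = (*cand, frame, seq)
                start_idx = None
            elif not require_atg:
                continue
        # re-scan for ATG starts inside open stretches: every ATG can start
        # an ORF ending at the same stop, so only the first ATG per stretch
        # matters for "longest"; handled above.
    if best is None:
        return None
    neg_len, _, start_in_frame, frame, seq = best
    length = -neg_len
    s, e = start_in_frame, start_in_frame + length
    cds = seq[s:e]
    if frame > 0:
        start, end = s, e
    else:  # map back onto the forward strand
        start, end = len(sequence) - e, len(sequence) - s
    return CodingRegion(
        source_id=source_id, frame=frame, start=start, end=end, cds=cds
    )


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


_PROT_ALIGNER = _protein_aligner()


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon pairs from a protein-level global alignment of two CDSs.

    Gap columns (in either sequence) are excluded.  Raises on empty
    translations or lengths not divisible by 3.
    """
    prot_a, prot_b = translate(cds_a), translate(cds_b)
    for p in (prot_a, prot_b):
        if not p or p.strip("*") == "":
            raise ValueError("empty translation")
    # trailing stops are not aligned
    pa = prot_a[:-1] if prot_a.endswith("*") else prot_a
    pb = prot_b[:-1] if prot_b.endswith("*") else prot_b
    if "*" in pa or "*" in pb:
        raise ValueError("internal stop codon in CDS")
    aln = _PROT_ALIGNER.align(pa, pb)[0]
    blocks_a, blocks_b = aln.aligned
    pairs = []
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for k in range(a1 - a0):
            ca = cds_a[3 * (a0 + k) : 3 * (a0 + k) + 3]
            cb = cds_b[3 * (b0 + k) : 3 * (b0 + k) + 3]
            pairs.append((ca, cb))
    return pairs


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over minimal paths."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    if k == 1:
        i = diff_pos[0]
        syn = (
            codon_b not in STOP_CODONS
            and codon_a not in STOP_CODONS
            and CODON_TO_AA[codon_a] == CODON_TO_AA[codon_b]
        )
        return (1.0, 0.0) if syn else (0.0, 1.0)
    sd = nd = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        path_sd = path_nd = 0.0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if (
                current not in STOP_CODONS
                and nxt not in STOP_CODONS
                and CODON_TO_AA[current] == CODON_TO_AA[nxt]
            ):
                path_sd += 1
            else:
                path_nd += 1
            current = nxt
        sd += path_sd
        nd += path_nd
        n_paths += 1
    return sd / n_paths, nd / n_paths


def _jc_correct(p: float) -> float:
    v = -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))
    return 0.0 if v == 0 else v


def ng86_kaks(codon_pairs, id_a: str = "a", id_b: str = "b") -> KaKsPair:
    """NG86 Ks/Kn/omega for an aligned codon pair list."""
    pairs = [
        (ca, cb)
        for ca, cb in codon_pairs
        if "-" not in ca and "-" not in cb
    ]
    if not pairs:
        raise ValueError("no compared codons")
    s_a = sum(SYN_SITES[ca] for ca, _ in pairs)
    s_b = sum(SYN_SITES[cb] for _, cb in pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for ca, cb in pairs:
        ds, dn = _pathway_diffs(ca, cb)
        Sd += ds
        Nd += dn
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return KaKsPair(
            id_a, id_b, len(pairs), S, N, Sd, Nd,
            None, None, None, valid=False,
            reason=f"proportion of differences too large (ps={ps:.3f}, pn={pn:.3f})",
        )
    Ks = _jc_correct(ps)
    Kn = _jc_correct(pn)
    if Ks == 0.0:
        omega: float = OMEGA_SENTINEL
        removed = True
    else:
        omega = Kn / Ks
        removed = False
    return KaKsPair(
        id_a, id_b, len(pairs), S, N, Sd, Nd, Ks, Kn, omega,
        removed=removed,
        positive_selection=bool(not removed and omega > 1.0),
    )


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "codons": p.codons_compared,
                "S_sites": p.S_sites,
                "N_sites": p.N_sites,
                "Sd": p.Sd,
                "Nd": p.Nd,
                "Ks": p.Ks,
                "Kn": p.Kn,
                "omega": p.omega,
                "removed": p.removed,
                "positive_selection": p.positive_selection,
                "valid": p.valid,
            }
            for p in pairs
        ]
    )


def _kde_peak(values: np.ndarray) -> float:
    """Mode of a Gaussian kernel density estimate (standard for Ks peaks)."""
    from scipy.stats import gaussian_kde

    if len(values) < 5 or np.allclose(values, values[0]):
        return float(np.median(values))
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def screen_selection(pairs_by_group: dict, bin_width: float = 0.01) -> dict:
    """Per-group Ks histogram and selection summary.

    ``pairs_by_group`` maps a species-pair label (e.g. "parent_s:parent_t")
    to a list of :class:`KaKsPair`.  Removed (omega = 99) and invalid pairs
    are excluded from the histograms; histogram counts sum to the number of
    retained pairs.
    """
    out = {}
    for group in sorted(pairs_by_group):
        pairs = pairs_by_group[group]
        kept = [p for p in pairs if p.valid and not p.removed]
        ks = np.array([p.Ks for p in kept], dtype=float)
        if len(ks):
            n_bins = int(np.floor(ks.max() / bin_width)) + 1
            edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
            counts, edges = np.histogram(ks, bins=edges)
            hist = pd.DataFrame(
                {"bin_left": edges[:-1], "count": counts}
            )
            peak = float(edges[int(np.argmax(counts))])
            peak_kde = _kde_peak(ks)
        else:
            hist = pd.DataFrame({"bin_left": [], "count": []})
            peak = float("nan")
            peak_kde = float("nan")
        out[group] = {
            "n_pairs": len(pairs),
            "n_removed": sum(1 for p in pairs if p.removed),
            "n_invalid": sum(1 for p in pairs if not p.valid),
            "n_kept": len(kept),
            "n_ks_below_0.01": int((ks < 0.01).sum()) if len(ks) else 0,
            "n_positive_selection": sum(
                1 for p in kept if p.positive_selection
            ),
            "ks_mean": float(ks.mean()) if len(ks) else float("nan"),
            "ks_peak": peak,
            "ks_peak_kde": peak_kde,
            "histogram": hist,
        }
    return out
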