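"""Universal genetic code tables shared by the simulator and the Ka/Ks module."""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))

#: codon -> one-letter amino acid, with '*' for stops
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) with '*' for stop codons."""
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def has_internal_stop(cds: str) -> bool:
    aa = translate(cds)
    return "*" in aa[:-1] or (len(aa) > 0 and aa[-1] == "*" and "*" in aa[:-1])


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three single-base changes at ``pos`` that are synonymous.

    Changes producing a stop codon count as nonsynonymous, so the synonymous
    plus nonsynonymous site fractions of every codon sum to exactly 3.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
            syn += 1
    return syn / 3.0

#: codon -> number of synonymous sites (0..3); nonsynonymous sites = 3 - value
SYN_SITES = {c: sum(_syn_fraction(c, p) for p in range(3)) for c in SENSE_CODONS}
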