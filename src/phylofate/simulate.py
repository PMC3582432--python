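"""Synthetic allotetraploid transcriptome generator.

Emulates the study system: an allotetraploid ("polyploid", A) formed ~0.2 Myr
ago from two diploid parents ("parent_s", B, the maternal S-genome donor and
"parent_t", C, the paternal T-genome donor) plus a distant outgroup (O).
Coding sequences evolve along the species tree ((S,T),outgroup) with
configurable synonymous divergence (Ks) per split and per-gene omega
(Kn/Ks); the polyploid receives both parental gene copies, further evolved by
a small post-hybridization Ks, and a per-gene fate (both copies retained, one
copy lost, or one copy silenced) decides which copies emit reads.

Expression levels are lognormal on a RPKM-like scale; a configurable minority
of genes is differentially expressed.  Reads are uniformly placed substrings
with optional substitution errors and homopolymer indels, sampled per species
proportional to expression times transcript length.  Every emitted object is
tracked in a truth table so downstream stages can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate

SPECIES = ("polyploid", "parent_s", "parent_t", "outgroup")

#: duplicate-gene fates; silencing and loss both emit zero reads for the
#: affected copy but stay distinct in the truth table (transcriptome data
#: alone cannot tell them apart).
FATES = ("both_retained", "s_only", "t_only", "silenced_s", "silenced_t")

_STOP_TAIL = "TAA"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic transcriptome.

    Defaults encode the system the pipeline targets: parental orthologs peak
    at pairwise Ks ~0.09, the outgroup at ~0.27, post-hybridization
    divergence Ks ~0.01, mostly-conserved expression with a minority of
    differential genes, and 454-scale read lengths.
    """

    n_genes: int = 500
    cds_len_range: tuple[int, int] = (600, 1500)
    branch_ks: dict = field(
        default_factory=lambda: {
            "parent_split": 0.09,
            "outgroup_split": 0.27,
            "post_hybridization": 0.01,
        }
    )
    # per-gene omega: lognormal background, optional fraction with omega > 1
    # on the parental split (positive selection predating hybridization).
    per_gene_omega: dict = field(
        default_factory=lambda: {
            "log10_mean": -0.8,
            "log10_sd": 0.25,
            "frac_positive": 0.03,
            "positive_omega": 1.5,
        }
    )
    fate_probs: dict = field(
        default_factory=lambda: {
            "both_retained": 0.10,
            "s_only": 0.40,
            "t_only": 0.40,
            "silenced_s": 0.05,
            "silenced_t": 0.05,
        }
    )
    # fraction of genes whose parents are sequence-identical: these reproduce
    # the "collapsed"/non-distinguishable class of an allopolyploid assembly.
    frac_identical_parents: float = 0.2
    expr_lognormal: tuple[float, float] = (1.0, 0.6)  # mean, sd of log10 level
    frac_differential: float = 0.15
    fold_change: float = 4.0
    coverage: float = 20.0  # mean reads per gene per species
    read_len: int = 350
    subst_error_rate: float = 0.001
    homopolymer_indel_rate: float = 0.0
    seed: int = 42

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.cds_len_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ValueError("cds_len_range must be an interval of multiples of 3")
        if set(self.fate_probs) != set(FATES):
            raise ValueError(f"fate_probs must have exactly the keys {FATES}")
        total = sum(self.fate_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fate_probs must sum to 1 (got {total})")
        for name, value in self.branch_ks.items():
            if value < 0:
                raise ValueError(f"branch_ks[{name}] must be >= 0")
        for rate in (
            self.frac_identical_parents,
            self.frac_differential,
            self.subst_error_rate,
            self.homopolymer_indel_rate,
        ):
            if rate < 0:
                raise ValueError("rates and fractions must be >= 0")
        if self.coverage < 0 or self.read_len < 1 or self.fold_change <= 0:
            raise ValueError("invalid coverage, read_len or fold_change")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("cds_len_range", "expr_lognormal"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class TranscriptRecord:
    """One expressed (or silenced) gene copy in one species."""

    id: str
    species: str
    gene: str
    subgenome: str | None  # "S"/"T" for polyploid copies
    sequence: str
    expression: float


@dataclass
class ReadRecord:
    """A species-labeled read, carrying simulation ground truth."""

    id: str
    species: str
    sequence: str
    truth_gene: str | None = None
    truth_subgenome: str | None = None


@dataclass
class FamilySet:
    """Per-species transcript sets plus the per-gene truth table."""

    transcripts: dict  # species -> list[TranscriptRecord]
    truth: pd.DataFrame
    config: SimulationConfig


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG followed by random sense codons (no internal stops)."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body)


def evolve_cds(ancestor: str, branch_ks: float, omega: float, seed) -> str:
    """Evolve a CDS so that the expected synonymous divergence is ``branch_ks``.

    Substitution proposals are uniform over positions and alternative bases
    (Jukes-Cantor-like equal exchange); synonymous proposals are accepted
    with probability min(1, 1/omega), nonsynonymous ones with probability
    min(1, omega) (so the nonsynonymous/synonymous acceptance ratio is
    omega for any omega >= 0), and proposals creating a stop codon are
    always rejected.  The proposal count is scaled so the expected
    number of accepted synonymous changes is branch_ks x (synonymous
    sites) and of nonsynonymous changes omega x branch_ks x (nonsynonymous
    sites); an NG86 estimate on (ancestor, result) therefore recovers
    branch_ks at low divergence.
    """
    if branch_ks < 0 or omega < 0:
        raise ValueError("branch_ks and omega must be >= 0")
    if len(ancestor) % 3:
        raise ValueError("ancestor length must be divisible by 3")
    aa = translate(ancestor)
    if "*" in aa:
        raise ValueError("ancestor contains an internal stop codon")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if branch_ks == 0:
        return ancestor
    accept_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    accept_non = min(1.0, omega)
    seq = list(ancestor)
    length = len(seq)
    n_events = rng.poisson(branch_ks * length / accept_syn)
    for _ in range(n_events):
        pos = int(rng.integers(length))
        alts = [b for b in "ACGT" if b != seq[pos]]
        new = alts[int(rng.integers(3))]
        start = pos - pos % 3
        old_codon = "".join(seq[start : start + 3])
        new_codon = old_codon[: pos % 3] + new + old_codon[pos % 3 + 1 :]
        if new_codon in STOP_CODONS:
            continue  # rejected: stop codons are never introduced
        if CODON_TO_AA[new_codon] == CODON_TO_AA[old_codon]:
            if accept_syn >= 1.0 or rng.random() < accept_syn:
                seq[pos] = new
        elif rng.random() < accept_non:
            seq[pos] = new
    return "".join(seq)


def _draw_fate(rng: np.random.Generator, fate_probs: dict) -> str:
    probs = np.array([fate_probs[f] for f in FATES])
    return FATES[int(rng.choice(len(FATES), p=probs / probs.sum()))]


def generate_family_set(config: SimulationConfig) -> FamilySet:
    """Evolve gene families along ((S,T),outgroup) and apply per-gene fates."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ks = config.branch_ks
    om = config.per_gene_omega
    lo, hi = config.cds_len_range
    transcripts: dict[str, list[TranscriptRecord]] = {sp: [] for sp in SPECIES}
    rows = []
    for g in range(config.n_genes):
        gene = f"g{g:05d}"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        ancestor = random_cds(rng, n_codons)
        identical_parents = bool(rng.random() < config.frac_identical_parents)
        positive = bool(rng.random() < om.get("frac_positive", 0.0))
        omega_parent = float(
            om["positive_omega"]
            if positive
            else 10 ** rng.normal(om["log10_mean"], om["log10_sd"])
        )
        omega_post = float(
            min(10 ** rng.normal(om["log10_mean"], om["log10_sd"]), 0.99)
        )
        half_parent = ks["parent_split"] / 2.0
        # outgroup branch chosen so the polyploid-to-outgroup pairwise Ks
        # equals outgroup_split exactly (the comparison the screens report)
        out_branch = max(
            ks["outgroup_split"] - half_parent - ks["post_hybridization"],
            0.0,
        )
        if identical_parents:
            seq_s = seq_t = ancestor
        else:
            seq_s = evolve_cds(ancestor, half_parent, omega_parent, rng)
            seq_t = evolve_cds(ancestor, half_parent, omega_parent, rng)
        seq_o = evolve_cds(ancestor, out_branch, omega_parent, rng)
        seq_as = evolve_cds(seq_s, ks["post_hybridization"], omega_post, rng)
        seq_at = evolve_cds(seq_t, ks["post_hybridization"], omega_post, rng)

        fate = _draw_fate(rng, config.fate_probs)
        base = 10 ** rng.normal(*config.expr_lognormal)
        differential = bool(rng.random() < config.frac_differential)
        fold = config.fold_change
        # dosage-compensated defaults: the polyploid's total matches a parent
        expr = {"parent_s": base, "parent_t": base, "outgroup": base}
        present = {"S": fate not in ("t_only",), "T": fate not in ("s_only",)}
        expressed = {
            "S": fate in ("both_retained", "s_only", "silenced_t"),
            "T": fate in ("both_retained", "t_only", "silenced_s"),
        }
        copy_expr = {"S": 0.0, "T": 0.0}
        diff_mode = ""
        if fate == "both_retained":
            copy_expr = {"S": base / 2, "T": base / 2}
            if differential:
                up = "S" if rng.random() < 0.5 else "T"
                dn = "T" if up == "S" else "S"
                copy_expr[up] = base * fold / (1 + fold)
                copy_expr[dn] = base / (1 + fold)
                diff_mode = f"homeolog_bias_{up}"
        else:
            which = "S" if expressed["S"] else "T"
            copy_expr[which] = base
            if differential:
                direction = fold if rng.random() < 0.5 else 1.0 / fold
                copy_expr[which] = base * direction
                diff_mode = "polyploid_up" if direction > 1 else "polyploid_down"

        seqs = {"S": seq_as, "T": seq_at}
        ids = {}
        for sub in ("S", "T"):
            if present[sub]:
                tid = f"{gene}_A{sub}"
                ids[sub] = tid
                transcripts["polyploid"].append(
                    TranscriptRecord(
                        tid, "polyploid", gene, sub,
                        seqs[sub] + _STOP_TAIL,
                        copy_expr[sub] if expressed[sub] else 0.0,
                    )
                )
            else:
                ids[sub] = ""
        for sp, seq in (("parent_s", seq_s), ("parent_t", seq_t), ("outgroup", seq_o)):
            transcripts[sp].append(
                TranscriptRecord(
                    f"{gene}_{sp}", sp, gene, None, seq + _STOP_TAIL, expr[sp]
                )
            )
        rows.append(
            {
                "gene": gene,
                "fate": fate,
                "identical_parents": identical_parents,
                "cds_len": n_codons * 3,
                "omega_parent": omega_parent,
                "omega_post": omega_post,
                "positive_selection": positive,
                "differential": differential,
                "diff_mode": diff_mode,
                "base_expression": base,
                "seq_polyploid_S": ids["S"],
                "seq_polyploid_T": ids["T"],
                "seq_parent_s": f"{gene}_parent_s",
                "seq_parent_t": f"{gene}_parent_t",
                "seq_outgroup": f"{gene}_outgroup",
                "expr_polyploid_S": copy_expr["S"] if expressed["S"] else 0.0,
                "expr_polyploid_T": copy_expr["T"] if expressed["T"] else 0.0,
                "expr_parent_s": expr["parent_s"],
                "expr_parent_t": expr["parent_t"],
                "expr_outgroup": expr["outgroup"],
            }
        )
    truth = pd.DataFrame(rows)
    return FamilySet(transcripts=transcripts, truth=truth, config=config)


def _mutate_read(seq: str, rng: np.random.Generator, config: SimulationConfig) -> str:
    out = seq
    if config.subst_error_rate > 0:
        n_err = rng.binomial(len(out), config.subst_error_rate)
        if n_err:
            chars = list(out)
            positions = rng.choice(len(chars), size=n_err, replace=False)
            for pos in positions:
                alts = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = alts[int(rng.integers(3))]
            out = "".join(chars)
    if config.homopolymer_indel_rate > 0:
        chars = []
        i = 0
        while i < len(out):
            j = i
            while j < len(out) and out[j] == out[i]:
                j += 1
            run = out[i:j]
            if j - i >= 2 and rng.random() < config.homopolymer_indel_rate:
                run = run + out[i] if rng.random() < 0.5 else run[:-1]
            chars.append(run)
            i = j
        out = "".join(chars)
    return out


def sample_reads(
    family: FamilySet, config: SimulationConfig | None = None, seed=None
) -> dict:
    """Sample reads per species proportional to expression x transcript length.

    Returns ``{species: [ReadRecord, ...]}``.  Each species library draws
    ``round(coverage * n_genes)`` reads multinomially across its expressed
    copies; silenced or lost copies emit zero reads.
    """
    config = config or family.config
    if seed is None:
        seed = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: dict[str, list[ReadRecord]] = {}
    for sp in SPECIES:
        copies = family.transcripts[sp]
        weights = np.array([t.expression * len(t.sequence) for t in copies])
        out: list[ReadRecord] = []
        total = int(round(config.coverage * config.n_genes))
        if weights.sum() > 0 and total > 0:
            counts = rng.multinomial(total, weights / weights.sum())
            idx = 0
            for t, n in zip(copies, counts):
                for _ in range(int(n)):
                    if len(t.sequence) <= config.read_len:
                        raw = t.sequence
                    else:
                        start = int(
                            rng.integers(len(t.sequence) - config.read_len + 1)
                        )
                        raw = t.sequence[start : start + config.read_len]
                    out.append(
                        ReadRecord(
                            id=f"{sp}_read{idx:06d}",
                            species=sp,
                            sequence=_mutate_read(raw, rng, config),
                            truth_gene=t.gene,
                            truth_subgenome=t.subgenome,
                        )
                    )
                    idx += 1
        reads[sp] = out
    return reads


# ---------------------------------------------------------------------------
# file output

def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def simulate_to_dir(config: SimulationConfig, outdir) -> FamilySet:
    """Run the generator and write FASTA / truth TSV / config JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    family = generate_family_set(config)
    reads = sample_reads(family)
    for sp in SPECIES:
        write_fasta(family.transcripts[sp], outdir / f"transcripts_{sp}.fasta")
        write_fasta(reads[sp], outdir / f"reads_{sp}.fasta")
    family.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    read_rows = [
        {
            "read_id": r.id,
            "species": r.species,
            "truth_gene": r.truth_gene,
            "truth_subgenome": r.truth_subgenome or "",
        }
        for sp in SPECIES
        for r in reads[sp]
    ]
    pd.DataFrame(read_rows).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return family
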