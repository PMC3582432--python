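"""End-to-end orchestration: simulate -> assemble -> cluster -> align ->
tree -> classify -> homeolog -> expression -> Ka/Ks, with a per-stage
attrition funnel and a machine-readable run report.

Every stage writes its outputs under the run directory (FASTA, aligned
FASTA, Newick, TSV, JSON) so stages can be re-run independently; when the
run starts from the simulator, the truth table is used at the end to score
topology recovery, origin assignment and differential-expression calls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clu
from . import expression as expr
from . import kaks as kk
from . import msa
from .homeolog import assign_origin
from .njtree import (
    DistanceError,
    Node,
    bootstrap_support,
    filter_by_support,
    root_at_outgroup,
)
from .simulate import (
    ReadRecord,
    SimulationConfig,
    simulate_to_dir,
    sample_reads,
    generate_family_set,
)
from .topology import (
    classify_topology,
    collapse_short_branches,
    species_topology,
    tally_topologies,
)

log = logging.getLogger("phylofate")

INGROUP = ("polyploid", "parent_s", "parent_t")
ALL_SPECIES = (*INGROUP, "outgroup")

#: truth fate -> implied topology category (for scoring synthetic runs)
FATE_TO_CATEGORY = {
    "both_retained": "AB_AC",
    "s_only": "AB_C",
    "silenced_t": "AB_C",
    "t_only": "AC_B",
    "silenced_s": "AC_B",
}


def _subconfig(cls):
    return field(default_factory=cls)


@dataclass
class AssemblyParams:
    identity: float = 97.0
    cross_identity: float = 95.0
    min_overlap: int = 40
    min_contig_len: int = 40
    min_contig_reads: int = 3
    split_collapsed: bool = True
    min_depth: int = 4
    min_af: float = 0.8
    map_min_identity: float = 90.0


@dataclass
class AlignParams:
    min_overlap: int = 100
    min_identity: float = 75.0
    engine: str = "builtin"
    external_cmd: str | None = None
    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    max_per_species: int = 1
    max_polyploid: int = 2
    outgroup_min_overlap: int = 100
    outgroup_min_identity: float = 70.0


@dataclass
class TreeParams:
    model: str = "JC69"
    bootstrap: int = 1000
    support_cutoff: float = 60.0
    ml_cmd: str | None = None  # external maximum-likelihood hook


@dataclass
class TopologyParams:
    branch_cutoff: float = 0.01


@dataclass
class HomeologParams:
    min_identity: float = 90.0
    min_overlap: int = 60


@dataclass
class ExpressionParams:
    min_reads: int = 5
    r_cutoff: float = 7.0


@dataclass
class KaksParams:
    bin_width: float = 0.01
    require_atg: bool = True


@dataclass
class PipelineConfig:
    """All stage parameters; ``seed`` drives every random draw."""

    seed: int = 42
    sim: SimulationConfig = _subconfig(SimulationConfig)
    assembly: AssemblyParams = _subconfig(AssemblyParams)
    alignment: AlignParams = _subconfig(AlignParams)
    tree: TreeParams = _subconfig(TreeParams)
    topology: TopologyParams = _subconfig(TopologyParams)
    homeolog: HomeologParams = _subconfig(HomeologParams)
    expression: ExpressionParams = _subconfig(ExpressionParams)
    kaks: KaksParams = _subconfig(KaksParams)

    def __post_init__(self):
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "sim": SimulationConfig,
            "assembly": AssemblyParams,
            "alignment": AlignParams,
            "tree": TreeParams,
            "topology": TopologyParams,
            "homeolog": HomeologParams,
            "expression": ExpressionParams,
            "kaks": KaksParams,
        }
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {"seed": data.get("seed", 42)}
        for key, section_cls in sections.items():
            if key not in data:
                continue
            sub = data[key]
            if key == "sim":
                kwargs[key] = SimulationConfig.from_dict(sub)
                continue
            known = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(sub) - known
            if bad:
                raise ValueError(f"unknown config keys in {key}: {sorted(bad)}")
            kwargs[key] = section_cls(**sub)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def apply_overrides(config: PipelineConfig, overrides: dict) -> PipelineConfig:
    """Apply dotted-path overrides, e.g. {"tree.bootstrap": 100}."""
    data = config.to_dict()
    for path, value in overrides.items():
        parts = path.split(".")
        node = data
        for part in parts[:-1]:
            if part not in node:
                raise ValueError(f"unknown config path {path!r}")
            node = node[part]
        if parts[-1] not in node:
            raise ValueError(f"unknown config path {path!r}")
        node[parts[-1]] = value
    return PipelineConfig.from_dict(data)


# ---------------------------------------------------------------------------
# funnel bookkeeping


class Funnel:
    def __init__(self):
        self.stages: list[dict] = []

    def record(self, stage: str, n_in: int, reasons: Counter):
        n_discarded = sum(reasons.values())
        self.stages.append(
            {
                "stage": stage,
                "n_in": n_in,
                "n_out": n_in - n_discarded,
                "n_discarded": n_discarded,
                "reasons": dict(sorted(reasons.items())),
            }
        )
        log.info(
            "stage %-12s in=%d out=%d discarded=%s",
            stage, n_in, n_in - n_discarded, dict(reasons),
        )

    def table(self) -> pd.DataFrame:
        rows = []
        for st in self.stages:
            if st["reasons"]:
                for reason, n in st["reasons"].items():
                    rows.append({**{k: st[k] for k in ("stage", "n_in", "n_out")},
                                 "reason": reason, "n_reason": n})
            else:
                rows.append({**{k: st[k] for k in ("stage", "n_in", "n_out")},
                             "reason": "", "n_reason": 0})
        return pd.DataFrame(rows)


def funnel_report(stage_logs) -> pd.DataFrame:
    """Cluster-attrition table; reasons partition each stage's discards."""
    funnel = Funnel()
    funnel.stages = list(stage_logs)
    return funnel.table()


# ---------------------------------------------------------------------------
# helpers


def _contig_species(contig_id: str) -> str:
    for sp in ALL_SPECIES:
        if contig_id.startswith(sp + "_"):
            return sp
    raise ValueError(f"cannot infer species from contig id {contig_id!r}")


def _contig_to_json(contig: clu.Contig) -> dict:
    return {
        "id": contig.id,
        "species": contig.species,
        "consensus": contig.consensus,
        "members": contig.members,
        "depth_profile": contig.depth_profile,
        "placements": {k: [v[0], v[1]] for k, v in contig.placements.items()},
    }


def _contig_from_json(data: dict) -> clu.Contig:
    return clu.Contig(
        id=data["id"],
        species=data["species"],
        consensus=data["consensus"],
        members=data["members"],
        depth_profile=data["depth_profile"],
        placements={k: (v[0], v[1]) for k, v in data["placements"].items()},
    )


def save_contigs(contigs_by_species: dict, outdir: Path) -> None:
    for sp, contigs in contigs_by_species.items():
        with open(outdir / f"contigs_{sp}.fasta", "w") as fh:
            for c in contigs:
                fh.write(f">{c.id}\n{c.consensus}\n")
    with open(outdir / "contigs.json", "w") as fh:
        json.dump(
            _jsonable(
                {
                    sp: [_contig_to_json(c) for c in contigs]
                    for sp, contigs in contigs_by_species.items()
                }
            ),
            fh,
        )


def load_contigs(outdir: Path) -> dict:
    with open(outdir / "contigs.json") as fh:
        data = json.load(fh)
    return {sp: [_contig_from_json(c) for c in items] for sp, items in data.items()}


def load_reads(outdir: Path) -> dict:
    from Bio import SeqIO

    truth = {}
    truth_path = outdir / "truth_reads.tsv"
    if truth_path.exists():
        df = pd.read_csv(truth_path, sep="\t", keep_default_na=False)
        truth = {
            r.read_id: (r.truth_gene, r.truth_subgenome or None)
            for r in df.itertuples()
        }
    reads = {}
    for sp in ALL_SPECIES:
        path = outdir / f"reads_{sp}.fasta"
        if not path.exists():
            continue
        out = []
        for rec in SeqIO.parse(str(path), "fasta"):
            gene, sub = truth.get(rec.id, (None, None))
            out.append(
                ReadRecord(
                    id=rec.id, species=sp, sequence=str(rec.seq).upper(),
                    truth_gene=gene, truth_subgenome=sub,
                )
            )
        reads[sp] = out
    return reads


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path):
    family = simulate_to_dir(config.sim, outdir)
    reads = sample_reads(family)
    return family, reads


def stage_assemble(config: PipelineConfig, outdir: Path, reads: dict) -> dict:
    """Per-species read clustering and consensus contigs."""
    a = config.assembly
    contigs_by_species = {}
    membership_rows = []
    for sp in ALL_SPECIES:
        contigs, membership = clu.species_assembly(
            reads.get(sp, []),
            species=sp,
            threshold=a.identity,
            min_overlap=a.min_overlap,
            min_contig_len=a.min_contig_len,
            min_contig_reads=a.min_contig_reads,
        )
        contigs_by_species[sp] = contigs
        membership_rows.extend(
            {"read_id": rid, "contig_id": cid} for rid, cid in membership.items()
        )
        log.info("assembled %s: %d reads -> %d contigs",
                 sp, len(reads.get(sp, [])), len(contigs))
    pd.DataFrame(membership_rows).to_csv(
        outdir / "membership.tsv", sep="\t", index=False
    )
    save_contigs(contigs_by_species, outdir)
    return contigs_by_species


def stage_collapse(config: PipelineConfig, outdir: Path, contigs_by_species, reads):
    """Collapse detection on the polyploid assembly, then phasing split."""
    a = config.assembly
    snps, report = clu.detect_collapse(
        contigs_by_species["polyploid"],
        reads,
        min_depth=a.min_depth,
        min_af=a.min_af,
        map_min_identity=a.map_min_identity,
    )
    snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    report.to_csv(outdir / "collapse.tsv", sep="\t", index=False)
    if a.split_collapsed:
        split = []
        for contig in contigs_by_species["polyploid"]:
            split.extend(clu.split_polymorphic_contig(contig))
        contigs_by_species = dict(contigs_by_species)
        contigs_by_species["polyploid"] = split
        save_contigs(contigs_by_species, outdir)
    return snps, report, contigs_by_species


def stage_clusters(config: PipelineConfig, outdir: Path, contigs_by_species,
                   funnel: Funnel):
    """Cross-species clustering plus outgroup attachment."""
    a, al = config.assembly, config.alignment
    # contigs still intra-polyploid polymorphic after splitting cannot be
    # phylogenetically analyzed (possible homeolog collapse)
    reasons = Counter()
    clean_poly = []
    for c in contigs_by_species["polyploid"]:
        if clu._polymorphic_columns(c):
            reasons["possible_collapse"] += 1
        else:
            clean_poly.append(c)
    ingroup = {
        "polyploid": clean_poly,
        "parent_s": contigs_by_species["parent_s"],
        "parent_t": contigs_by_species["parent_t"],
    }
    clusters = clu.cross_species_clusters(
        ingroup, threshold=a.cross_identity, min_overlap=a.min_overlap
    )
    n_in = len(clusters)
    outgroup = [(c.id, c.consensus) for c in contigs_by_species["outgroup"]]
    out_index = clu.KmerIndex([s for _, s in outgroup], k=12) if outgroup else None
    kept = []
    outgroup_hits = {}
    for cl in clusters:
        missing = set(INGROUP) - cl.species_present
        if missing:
            reasons["missing_species"] += 1
            continue
        query = max(cl.by_species("polyploid"), key=lambda c: len(c.consensus))
        hit = None
        if outgroup:
            hit = msa.attach_outgroup(
                query.consensus,
                outgroup,
                min_overlap=al.outgroup_min_overlap,
                min_identity=al.outgroup_min_identity,
                index=out_index,
            )
        if hit is None:
            reasons["missing_outgroup"] += 1
            continue
        outgroup_hits[cl.id] = hit
        kept.append(cl)
    funnel.record("clusters", n_in + reasons["possible_collapse"], reasons)
    rows = [
        {"cluster_id": cl.id, "contig_id": c.id, "species": c.species}
        for cl in kept
        for c in cl.contigs
    ] + [
        {"cluster_id": cid, "contig_id": hit[0], "species": "outgroup"}
        for cid, hit in outgroup_hits.items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    return kept, outgroup_hits


def stage_align(config: PipelineConfig, outdir: Path, clusters, outgroup_hits,
                funnel: Funnel):
    al = config.alignment
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    reasons = Counter()
    alignments = {}
    for cl in clusters:
        ids = [c.id for c in cl.contigs]
        seqs = [c.consensus for c in cl.contigs]
        species = [c.species for c in cl.contigs]
        oid, oseq, _, _ = outgroup_hits[cl.id]
        ids.append(oid)
        seqs.append(oseq)
        species.append("outgroup")
        try:
            aln = msa.align_cluster(
                seqs, ids=ids, species=species, cluster_id=cl.id,
                engine=al.engine, external_cmd=al.external_cmd,
                match=al.match, mismatch=al.mismatch,
                gap_open=al.gap_open, gap_extend=al.gap_extend,
            )
        except ValueError:
            reasons["alignment_failed"] += 1
            continue
        pruned, why = msa.prune_cluster(
            aln, max_per_species=al.max_per_species,
            max_polyploid=al.max_polyploid,
        )
        if pruned is None:
            reasons["missing_species"] += 1
            continue
        ok, why = msa.filter_alignment(
            pruned, min_overlap=al.min_overlap, min_identity=al.min_identity
        )
        if not ok:
            reasons[f"alignment_filter_{why.split(':')[0]}"] += 1
            continue
        alignments[cl.id] = pruned
        with open(aln_dir / f"{cl.id}.afa", "w") as fh:
            for sid, row in zip(pruned.ids, pruned.rows):
                fh.write(f">{sid}\n{row}\n")
    funnel.record("align_filter", len(clusters), reasons)
    return alignments


def stage_trees(config: PipelineConfig, outdir: Path, alignments, funnel: Funnel):
    t = config.tree
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    reasons = Counter()
    trees = {}
    summary = []
    for idx, (cid, aln) in enumerate(sorted(alignments.items())):
        seed = (config.seed * 1000003 + idx) % (2**31)
        try:
            tree, supports = bootstrap_support(
                aln, replicates=t.bootstrap, seed=seed, model=t.model
            )
        except DistanceError:
            reasons["distance_undefined"] += 1
            continue
        passed, min_support = filter_by_support(tree, t.support_cutoff)
        summary.append(
            {
                "cluster_id": cid,
                "passed": passed,
                "min_support": min_support if min_support is not None else "",
            }
        )
        with open(tree_dir / f"{cid}.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")
        if not passed:
            reasons["low_support"] += 1
            continue
        trees[cid] = tree
    funnel.record("support_filter", len(alignments), reasons)
    pd.DataFrame(summary).to_csv(outdir / "tree_summary.tsv", sep="\t", index=False)
    return trees


def stage_classify(config: PipelineConfig, outdir: Path, trees, funnel: Funnel):
    reasons = Counter()
    rows = []
    classified = {}
    for cid, tree in sorted(trees.items()):
        try:
            rooted = root_at_outgroup(tree)
        except ValueError:
            reasons["rooting_failed"] += 1
            continue
        collapsed = collapse_short_branches(
            rooted, config.topology.branch_cutoff
        )
        form = species_topology(collapsed)
        category = classify_topology(form)
        rows.append(
            {
                "cluster_id": cid,
                "canonical_form": form,
                "label": category.label,
                "n_polyploid_leaves": category.n_polyploid_leaves,
            }
        )
        if category.label == "unresolved":
            reasons["unresolved_polytomy"] += 1
            continue
        classified[cid] = (rooted, category)
    funnel.record("classify", len(trees), reasons)
    df = pd.DataFrame(
        rows, columns=["cluster_id", "canonical_form", "label",
                       "n_polyploid_leaves"]
    )
    df.to_csv(outdir / "topology.tsv", sep="\t", index=False)
    if len(df):
        tally = tally_topologies(df["label"].tolist())
        tally.to_csv(outdir / "topology_tally.tsv", sep="\t", index=False)
    return classified, df


def stage_homeolog(config: PipelineConfig, outdir: Path, classified,
                   consensus_by_id, funnel: Funnel):
    h = config.homeolog
    rows = []
    calls_by_cluster = {}
    reasons = Counter()
    for cid, (rooted, category) in sorted(classified.items()):
        calls = assign_origin(
            rooted, consensus_by_id,
            min_identity=h.min_identity, min_overlap=h.min_overlap,
        )
        calls_by_cluster[cid] = calls
        if not any(c.origin != "unassigned" for c in calls):
            reasons["no_confirmed_origin"] += 1
        for c in calls:
            rows.append(
                {
                    "cluster_id": cid,
                    "sequence_id": c.sequence_id,
                    "origin": c.origin,
                    "sister_species": c.sister_species or "",
                    "identity": round(c.identity, 2),
                    "overlap": c.overlap,
                    "tree_distance": round(c.tree_distance, 6),
                    "reason": c.reason,
                }
            )
    funnel.record("homeolog", len(classified), reasons)
    pd.DataFrame(
        rows, columns=["cluster_id", "sequence_id", "origin", "sister_species",
                       "identity", "overlap", "tree_distance", "reason"]
    ).to_csv(outdir / "homeologs.tsv", sep="\t", index=False)
    return calls_by_cluster


def _cluster_counts(clusters, outgroup_hits, contig_counts, libs):
    """Aggregate per-contig counts to per-cluster per-species counts."""
    rows = {}
    for cl in clusters:
        row = {}
        for sp in libs:
            ids = [c.id for c in cl.contigs if c.species == sp]
            row[sp] = int(
                contig_counts.loc[
                    [i for i in ids if i in contig_counts.index], sp
                ].sum()
            )
        rows[cl.id] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(libs)]


def stage_expression(config: PipelineConfig, outdir: Path, clusters,
                     outgroup_hits, contigs_by_species, reads,
                     classified, calls_by_cluster, collapse_report):
    e = config.expression
    membership = {}
    for sp in INGROUP:
        for c in contigs_by_species[sp]:
            for rid in c.members:
                membership[rid] = c.id
    libraries = {sp: [r.id for r in reads[sp]] for sp in INGROUP}
    contig_counts, totals = expr.count_reads(membership, libraries)
    # species-level expression per cluster
    cluster_counts = _cluster_counts(clusters, outgroup_hits, contig_counts,
                                     INGROUP)
    calls = expr.call_differential(
        cluster_counts, totals, min_reads=e.min_reads, r_cutoff=e.r_cutoff
    )
    lengths = {
        c.id: len(c.consensus)
        for sp in INGROUP
        for c in contigs_by_species[sp]
    }
    table = cluster_counts.join(calls)
    table.index.name = "cluster_id"
    table.to_csv(outdir / "expression.tsv", sep="\t")

    # homeolog pairs from dual-copy clusters with confirmed S and T origins
    by_cluster = {cl.id: cl for cl in clusters}
    pairs = []
    for cid, calls_list in sorted(calls_by_cluster.items()):
        origins = {c.origin: c.sequence_id for c in calls_list
                   if c.origin in ("S", "T")}
        if set(origins) != {"S", "T"}:
            continue
        cl = by_cluster[cid]
        parent_contigs = {
            sp: max(cl.by_species(sp), key=lambda c: len(c.consensus)).id
            for sp in ("parent_s", "parent_t")
            if cl.by_species(sp)
        }
        if len(parent_contigs) < 2:
            continue
        pairs.append(
            {
                "cluster": cid,
                "s_contig": origins["S"],
                "t_contig": origins["T"],
                "parent_s_contig": parent_contigs["parent_s"],
                "parent_t_contig": parent_contigs["parent_t"],
            }
        )
    pair_table, pair_summary = expr.compare_homeolog_pairs(
        pairs, contig_counts, lengths, totals,
        polyploid_lib="polyploid",
        min_reads=e.min_reads, r_cutoff=e.r_cutoff,
    )
    if len(pair_table):
        pair_table.to_csv(outdir / "homeolog_pairs.tsv", sep="\t", index=False)
    return contig_counts, totals, table, pair_table, pair_summary


def stage_kaks(config: PipelineConfig, outdir: Path, classified,
               calls_by_cluster, clusters, outgroup_hits, consensus_by_id,
               funnel: Funnel):
    k = config.kaks
    by_cluster = {cl.id: cl for cl in clusters}
    groups: dict[str, list] = defaultdict(list)
    reasons = Counter()
    orf_cache: dict[str, str | None] = {}

    def orf_of(seq_id: str) -> str | None:
        if seq_id not in orf_cache:
            region = kk.longest_orf_6frame(
                consensus_by_id[seq_id], source_id=seq_id,
                require_atg=k.require_atg,
            )
            orf_cache[seq_id] = region.cds if region else None
        return orf_cache[seq_id]

    def add_pair(group: str, id_a: str, id_b: str):
        cds_a, cds_b = orf_of(id_a), orf_of(id_b)
        if cds_a is None or cds_b is None:
            reasons["no_orf"] += 1
            return
        try:
            codons = kk.codon_align(cds_a, cds_b)
            groups[group].append(kk.ng86_kaks(codons, id_a, id_b))
        except ValueError:
            reasons["kaks_failed"] += 1

    for cid, (rooted, category) in sorted(classified.items()):
        cl = by_cluster[cid]
        origins = {c.origin: c.sequence_id for c in calls_by_cluster.get(cid, [])
                   if c.origin in ("S", "T")}
        parents = {
            sp: max(cl.by_species(sp), key=lambda c: len(c.consensus)).id
            for sp in ("parent_s", "parent_t")
            if cl.by_species(sp)
        }
        oid = outgroup_hits[cid][0]
        consensus_by_id.setdefault(oid, outgroup_hits[cid][1])
        if "parent_s" in parents and "parent_t" in parents:
            add_pair("parent_s:parent_t", parents["parent_s"],
                     parents["parent_t"])
        if "S" in origins and "parent_s" in parents:
            add_pair("polyploid_S:parent_s", origins["S"], parents["parent_s"])
        if "T" in origins and "parent_t" in parents:
            add_pair("polyploid_T:parent_t", origins["T"], parents["parent_t"])
        if {"S", "T"} <= set(origins):
            add_pair("polyploid_S:polyploid_T", origins["S"], origins["T"])
        poly = [c for c in cl.by_species("polyploid")]
        if poly:
            longest = max(poly, key=lambda c: len(c.consensus))
            add_pair("polyploid:outgroup", longest.id, oid)
    funnel.record("kaks", len(classified), reasons)
    all_pairs = [p for group in groups.values() for p in group]
    kk.pairs_to_frame(all_pairs).to_csv(outdir / "kaks.tsv", sep="\t",
                                        index=False)
    screen = kk.screen_selection(groups, bin_width=k.bin_width)
    for group, info in screen.items():
        safe = group.replace(":", "_vs_")
        info["histogram"].to_csv(outdir / f"ks_hist_{safe}.tsv", sep="\t",
                                 index=False)
    return groups, screen


# ---------------------------------------------------------------------------
# truth-based scoring


def _contig_truth(contigs_by_species, reads) -> dict:
    """contig id -> (majority truth gene, majority truth subgenome)."""
    read_truth = {
        r.id: (r.truth_gene, r.truth_subgenome)
        for sp in reads
        for r in reads[sp]
    }
    out = {}
    for sp, contigs in contigs_by_species.items():
        for c in contigs:
            genes = Counter()
            subs = Counter()
            for rid in c.members:
                gene, sub = read_truth.get(rid, (None, None))
                if gene:
                    genes[gene] += 1
                if sub:
                    subs[sub] += 1
            gene = genes.most_common(1)[0][0] if genes else None
            sub = subs.most_common(1)[0][0] if subs else None
            out[c.id] = (gene, sub)
    return out


def score_against_truth(truth: pd.DataFrame, contig_truth: dict,
                        topology_df: pd.DataFrame, clusters,
                        calls_by_cluster, expression_table: pd.DataFrame,
                        pair_table: pd.DataFrame) -> dict:
    """Recovery statistics for a synthetic run with known ground truth."""
    truth_by_gene = truth.set_index("gene")
    by_cluster = {cl.id: cl for cl in clusters}
    # cluster -> majority truth gene over member contigs
    cluster_gene = {}
    for cl in clusters:
        genes = Counter()
        for c in cl.contigs:
            g = contig_truth.get(c.id, (None, None))[0]
            if g:
                genes[g] += 1
        if genes:
            cluster_gene[cl.id] = genes.most_common(1)[0][0]

    confusion: dict[str, Counter] = defaultdict(Counter)
    n_match = n_scored = 0
    for row in topology_df.itertuples():
        if row.label in ("unresolved",) or row.cluster_id not in cluster_gene:
            continue
        gene = cluster_gene[row.cluster_id]
        if gene not in truth_by_gene.index:
            continue
        g = truth_by_gene.loc[gene]
        if g.identical_parents:
            continue  # truth category undefined when parents are identical
        expected = FATE_TO_CATEGORY[g.fate]
        confusion[expected][row.label] += 1
        n_scored += 1
        if row.label == expected:
            n_match += 1

    n_origin = n_origin_match = 0
    for cid, calls in calls_by_cluster.items():
        for c in calls:
            if c.origin not in ("S", "T"):
                continue
            truth_sub = contig_truth.get(c.sequence_id, (None, None))[1]
            if truth_sub is None:
                continue
            n_origin += 1
            if truth_sub == c.origin:
                n_origin_match += 1

    de = {"n_eligible": 0, "n_flagged": 0, "n_true_diff_eligible": 0,
          "n_true_diff_flagged": 0, "n_false_flagged": 0}
    if len(expression_table):
        for cid, row in expression_table.iterrows():
            if not row.get("eligible", False):
                continue
            gene = cluster_gene.get(cid)
            if gene is None or gene not in truth_by_gene.index:
                continue
            g = truth_by_gene.loc[gene]
            truly = bool(g.differential and str(g.diff_mode).startswith("polyploid"))
            de["n_eligible"] += 1
            if row["differential"]:
                de["n_flagged"] += 1
                if truly:
                    de["n_true_diff_flagged"] += 1
                else:
                    de["n_false_flagged"] += 1
            if truly:
                de["n_true_diff_eligible"] += 1

    pair_de = {"n_eligible": 0, "n_flagged": 0, "n_true_bias_eligible": 0,
               "n_true_bias_flagged": 0}
    if len(pair_table):
        for row in pair_table.itertuples():
            if not row.eligible:
                continue
            gene = cluster_gene.get(row.cluster)
            if gene is None or gene not in truth_by_gene.index:
                continue
            g = truth_by_gene.loc[gene]
            truly = bool(str(g.diff_mode).startswith("homeolog_bias"))
            pair_de["n_eligible"] += 1
            if row.differential:
                pair_de["n_flagged"] += 1
                if truly:
                    pair_de["n_true_bias_flagged"] += 1
            if truly:
                pair_de["n_true_bias_eligible"] += 1

    return {
        "topology": {
            "n_scored": n_scored,
            "n_match": n_match,
            "recovery_pct": (100.0 * n_match / n_scored) if n_scored else None,
            "confusion": {k: dict(v) for k, v in confusion.items()},
        },
        "origin": {
            "n_calls": n_origin,
            "n_match": n_origin_match,
            "accuracy_pct": (
                100.0 * n_origin_match / n_origin if n_origin else None
            ),
        },
        "differential_expression": de,
        "homeolog_pair_expression": pair_de,
    }


# ---------------------------------------------------------------------------
# driver


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages and return the machine-readable run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel = Funnel()

    family, reads = stage_simulate(config, outdir)
    contigs_by_species = stage_assemble(config, outdir, reads)
    snps, collapse_report, contigs_by_species = stage_collapse(
        config, outdir, contigs_by_species, reads
    )
    clusters, outgroup_hits = stage_clusters(
        config, outdir, contigs_by_species, funnel
    )
    alignments = stage_align(config, outdir, clusters, outgroup_hits, funnel)
    trees = stage_trees(config, outdir, alignments, funnel)
    classified, topology_df = stage_classify(config, outdir, trees, funnel)
    consensus_by_id = {
        c.id: c.consensus
        for sp in ALL_SPECIES
        for c in contigs_by_species[sp]
    }
    for cid, hit in outgroup_hits.items():
        consensus_by_id.setdefault(hit[0], hit[1])
    calls_by_cluster = stage_homeolog(
        config, outdir, classified, consensus_by_id, funnel
    )
    (contig_counts, totals, expression_table, pair_table,
     pair_summary) = stage_expression(
        config, outdir, clusters, outgroup_hits, contigs_by_species, reads,
        classified, calls_by_cluster, collapse_report,
    )
    kaks_groups, kaks_screen = stage_kaks(
        config, outdir, classified, calls_by_cluster, clusters, outgroup_hits,
        consensus_by_id, funnel,
    )

    n_dist = int((collapse_report["class"] == "parent_distinguishable").sum())
    n_contigs_poly = len(collapse_report)
    eligible = expression_table[expression_table["eligible"]]
    origin_counts = Counter(
        c.origin
        for calls in calls_by_cluster.values()
        for c in calls
        if c.origin in ("S", "T")
    )
    report: dict = {
        "config": config.to_dict(),
        "simulate": {
            "n_genes": config.sim.n_genes,
            "n_reads": {sp: len(reads[sp]) for sp in reads},
        },
        "assembly": {
            sp: len(contigs_by_species[sp]) for sp in contigs_by_species
        },
        "collapse": {
            "n_polyploid_contigs": n_contigs_poly,
            "n_parent_distinguishable": n_dist,
            "parent_distinguishable_pct": (
                100.0 * n_dist / n_contigs_poly if n_contigs_poly else None
            ),
            "n_polyploid_polymorphic": int(
                collapse_report["polyploid_polymorphic"].sum()
            ),
        },
        "clusters": {"n_analyzed": len(clusters)},
        "alignment": {"n_passed": len(alignments)},
        "trees": {"n_passed_support": len(trees)},
        "topology": {
            "n_classified": len(classified),
            "tally": (
                tally_topologies(topology_df["label"].tolist()).to_dict("records")
                if len(topology_df)
                else []
            ),
        },
        "homeolog": {
            "n_S": origin_counts.get("S", 0),
            "n_T": origin_counts.get("T", 0),
        },
        "expression": {
            "n_clusters": int(len(expression_table)),
            "n_eligible": int(len(eligible)),
            "n_differential": int(eligible["differential"].sum())
            if len(eligible)
            else 0,
            "conserved_pct": (
                100.0
                * (1 - eligible["differential"].mean())
                if len(eligible)
                else None
            ),
            "homeolog_pairs": pair_summary,
        },
        "kaks": {
            group: {k: v for k, v in info.items() if k != "histogram"}
            for group, info in kaks_screen.items()
        },
        "funnel": funnel.stages,
    }
    score = score_against_truth(
        family.truth,
        _contig_truth(contigs_by_species, reads),
        topology_df,
        clusters,
        calls_by_cluster,
        expression_table,
        pair_table,
    )
    report["truth_scoring"] = score
    report = _jsonable(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    funnel.table().to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    return report
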