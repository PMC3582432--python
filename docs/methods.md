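# Methods

This note documents the models behind `phylofate`, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical choices that pin down reproducible behavior.

## The synthetic allotetraploid transcriptome

### Species tree and sequence evolution

Gene families evolve on the fixed tree `((S, T), outgroup)`, with the
polyploid's two copies hanging off the modern S and T tips:

* the two parents each evolve `parent_split / 2` synonymous substitutions
  per synonymous site from the ingroup ancestor (default pairwise
  `parent_split` Ks = 0.09);
* the outgroup branch is `outgroup_split − parent_split/2 −
  post_hybridization` (default 0.215), chosen so the *polyploid-to-outgroup*
  pairwise Ks — the comparison the selection screens report — equals
  `outgroup_split` = 0.27 exactly;
* each polyploid copy evolves a further `post_hybridization` Ks (default
  0.01) from its parental tip.

`evolve_cds` uses a per-site categorical substitution process with equal
exchange rates (Jukes–Cantor-like). Proposals are uniform over positions
and alternative bases; a synonymous proposal is accepted with probability
min(1, 1/ω) and a nonsynonymous one with probability min(1, ω), so the
nonsynonymous/synonymous acceptance ratio equals ω for any ω ≥ 0, including
the positive-selection regime ω > 1. The proposal count is scaled so the
expected number of accepted synonymous changes is exactly
Ks × (NG86 synonymous sites). Proposals that would create a stop codon are
consumed and rejected rather than resampled: resampling conditions the
proposal distribution on non-stop changes and inflates the realized
synonymous rate by several percent, enough to bias the estimator
round-trip. With this process the NG86 estimator recovers configured Ks
values of 0.01–0.27 within a few percent on multi-kilobase pairs
(the residual upward drift at Ks = 0.01 comes from pathway averaging at
multi-hit codons and stays under ~3%).

Per-gene ω is lognormal (median ≈ 0.16, σ = 0.25 decades) — a typical
transcriptome-wide distribution — with a configurable fraction (default
3%) drawn as positively selected (ω = 1.5) on the parental split only;
post-hybridization branches always use a background draw capped below 1.
This places ω > 1 signal in parent-vs-parent and cross-subgenome
comparisons and none in polyploid-vs-own-parent comparisons.

A configurable fraction of genes (`frac_identical_parents`, default 0.2)
has sequence-identical parents. These genes reproduce the
"non-distinguishable" class that dominates real allopolyploid assemblies:
their polyploid contigs carry no inter-parent SNP, their trees collapse to
polytomies, and no fate can be recovered for them — which is the correct
behavior, not a failure mode.

### Fates and expression

Each gene draws one fate from `{both_retained, s_only, t_only, silenced_s,
silenced_t}` (defaults 0.10 / 0.40 / 0.40 / 0.05 / 0.05, mirroring a young
polyploid in which ~10% of resolvable clusters retain both expressed
homeologs). Lost copies are absent from the polyploid transcript set;
silenced copies are present with expression 0 — both emit zero reads, and
transcriptome data cannot tell them apart downstream.

Expression is lognormal on a log10 scale (mean 1.0, σ 0.6), identical
across species for conserved genes, and dosage-compensated: the polyploid's
total for a gene matches one parental allocation, split equally between
retained copies. A fraction `frac_differential` (default 0.15) of genes is
differential: dual-copy genes get an S:T bias of `fold_change` (default
4) with the total preserved; single-copy genes have the whole polyploid
gene scaled up or down by the fold change. The truth table records the
mode, so cross-species and homeolog-pair differential calls can each be
scored against the genes they are able to detect.

### Reads

Each species library draws `round(coverage × n_genes)` reads (default
coverage 20 reads/gene/species — enough that the ≥ 5-read eligibility rule
retains most genes while low-expression genes realistically drop out),
multinomially across copies with weight expression × transcript length.
Reads are uniform substrings of length 350 (a 454-scale read length) with
per-base substitution errors (default 0.001) and optional per-homopolymer
indels (default off, so the indel-free fast paths are exercised by
default). The generator does not model chromosome structure, introns,
intergenomic translocations, quality values, or length/quality
distributions of any particular instrument; passing tests therefore
demonstrate correctness of the analysis logic under idealized reads, not
robustness to every real-data artifact.

Determinism: all draws flow from a single integer seed through
`numpy.random.default_rng`; identical configs produce byte-identical
outputs.

## Assembly by identity-threshold clustering

Read assembly is deliberately simplified to the decision that the analysis
actually depends on: two sequences merge when their best overlap alignment
covers at least `min_overlap` (40 bp) columns at an identity *strictly
above* the threshold, and clusters are the single-linkage transitive
closure of that predicate. The strict inequality is load-bearing: groups
differing at exactly 3 sites per 100 bp (identity 97.0%) merge in a 95%
assembly and separate in a 97% assembly, which is the threshold phenomenon
the per-species default of 97% exploits.

Overlap identity is matches over aligned columns, counting internal gap
columns as mismatches. The implementation seeds the overlap with the
dominant shared-k-mer offset and aligns the implied window end-to-end by
edit distance (terminal non-matching columns trimmed); when no seed exists
it falls back to a full Smith–Waterman search. Above 60 input sequences an
exact all-pairs comparison is replaced by a shared-k-mer candidate
prefilter (FracMinHash-sampled 14-mers); below that limit the clustering
is exact, and property tests verify equality with a brute-force transitive
closure.

Consensus building star-aligns members to the longest read; members that
do not overlap the longest read attach in later rounds against the growing
consensus, so overlapping chains assemble end to end. Per-column majority
wins, ties break in A<C<G<T order, insertions relative to the reference
are dropped, and contigs from fewer than 3 reads or shorter than 40 bp are
discarded (sparse fragments give unreliable consensus and distance
estimates).

### Collapsed homeologs

At 97% identity with 40 bp overlaps, reads from two homeologs ~3.5%
apart merge almost surely through short high-identity overlaps — the
collapse problem the assembly sweep is designed around. The pipeline
handles it in two steps. `detect_collapse` maps all species' reads onto
each polyploid contig (best-contig edlib placement, ≥ 90% identity),
builds per-species pileups, calls a position an inter-parent SNP when both
parents have ≥ 4 reads with different major alleles at ≥ 80% frequency,
joins per-species calls across species with full-outer-join semantics
("no_coverage" where a species is absent), and classifies each contig as
`parent_distinguishable` (≥ 1 inter-parent SNP) or `non_distinguishable`.
A contig is `polyploid_polymorphic` when the polyploid's own pileup shows
a second allele at ≥ 2 reads and ≥ 20% frequency.

Second, polymorphic polyploid contigs are *split by phasing*: reads are
partitioned by their alleles at intra-contig polymorphic columns (seeded
at the deepest column, refined by agreement with the two haplotype
consensuses), and each haplotype becomes its own contig. At ~3.5%
divergence a 350 bp read covers ~10 phase-informative sites, so phasing is
near-perfect on error-free data. Contigs still polymorphic after splitting
are excluded from phylogenetic analysis with the funnel reason
`possible_collapse` — collapsed sequence cannot be placed in a species
tree.

The SNP-calling depth/frequency defaults (4 reads, 80%) are explicit
desk-scale stand-ins and are configurable.

## Clusters, alignment, and filters

Per-species contigs are joined across the three ingroup species by the
same clustering at 95% identity; clusters lacking any ingroup species are
discarded (`missing_species`). The outgroup homolog is the best-scoring
hit of the longest polyploid consensus against the outgroup assembly,
required to align over more than 100 bp at ≥ 70% identity
(`missing_outgroup` otherwise).

The builtin multiple aligner is progressive: a UPGMA guide tree on k-mer
distances, profiles merged by globally aligning their majority-consensus
strings with affine gaps (match 2, mismatch −2, open −5, extend −1) and
*free end gaps*. Free end gaps matter: cluster members are transcript
fragments covering different regions, and penalized end gaps systematically
misalign staggered fragments (this was measurable as a ~20-point drop in
topology recovery before the choice was pinned). An external aligner can
be substituted via a command template; the builtin keeps the pipeline
dependency-free.

An alignment passes when the columns covered by *every* row span ≥ 100 bp
and the mean of all pairwise identities (each over the pair's mutually
covered columns) is ≥ 75%. Pruning keeps, per parental/outgroup species,
the sequence maximizing the summed alignment score to the polyploid rows
(ties by id), and at most two polyploid rows ranked by score to the
parents; clusters missing one of the four species are discarded.

## Trees

Distances are Jukes–Cantor (default) or p-distances with pairwise deletion
of gap columns; a pair with p ≥ 0.75 makes the cluster undefined
(`distance_undefined`). Neighbor joining follows Saitou–Nei with the
standard Q criterion, deterministic tie-breaking by the smallest (i, j)
index pair, and negative branch estimates clamped to zero. Zero-length
internal branches of the reference tree are contracted before supports are
computed, so identical sequences yield a star rather than an arbitrary
tie-broken resolution with spurious 100% support.

Bootstrap resamples alignment columns with replacement; replicate
p-distances at or beyond the JC singularity are clamped just below 0.75 so
every replicate yields a tree. Each internal edge of the reference tree
receives the percentage of replicates containing its bipartition. The
default is 1000 replicates; the desk-scale runs (tests and the acceptance
script) use 100, which changes individual supports by a few points but not
the pass/fail behavior of well-resolved clusters. A tree fails when any
internal support is below 60% — supports are read from the reference
tree, not a consensus tree. Rooting bisects the single outgroup leaf's
branch.

## Topology classification

Internal branches shorter than 0.01 substitutions/site are contracted to
polytomies. This cutoff does double duty: it absorbs the arbitrary
resolution of effectively-zero branches (identical-parent genes become
`unresolved` instead of being misclassified), while true ingroup internal
branches at parental Ks 0.09 (~0.017 substitutions/site) stay above it
with ~3% loss from sampling noise. Leaves are relabeled A/B/C, the
outgroup (used only for rooting) is dropped, children are sorted lexically
at every level, and the canonical string is looked up in the registry of
named categories; polytomies are `unresolved`, and any other resolved
shape is reported systematically as `other:<canonical form>`, so an
arbitrary partition of shapes can be reconstructed from the output.

## Origin assignment, expression, selection

Origin calls use patristic distance on the rooted, support-filtered tree;
a distance tie (within 1e-12) is `unassigned: tie`, and calls are
confirmed by a ≥ 90% / ≥ 60 bp alignment to the nearest parent's contig.
On the default error-free conditions, confirmed calls match the true
subgenome ≥ 98% of the time.

Expression uses raw read counts with library totals (Stekel's original
formulation, natural logarithms); RPKM is used only for reporting and for
the homeolog-pair scatter correlations (Pearson on RPKM, with a log10
variant also reported, since the scale behind published correlations of
this kind is rarely stated). R = 0 exactly iff counts are proportional to
totals; note that R is invariant under *uniform* scaling of all library
totals (only the rates xⱼ/Nⱼ matter), so the guard tests exercise
single-total changes and joint count+total scaling instead. Reads spanning
collapsed homeologs count toward their single containing contig; there is
no fractional assignment and no multiple-testing correction.

NG86 counting: each codon position contributes (synonymous one-step
changes)/3 synonymous sites, with changes to stop codons counted as
nonsynonymous, so S + N = 3 per codon exactly; sites are averaged over the
two sequences; multi-hit codons average Sd/Nd over all minimal pathways
with equal weight (steps into or out of a stop codon count as
nonsynonymous). ps or pn ≥ 0.75 makes the pair invalid. ω = 99 whenever
Ks = 0 (including 0/0 for identical sequences); sentinel pairs are removed
from the screens. ORFs must be ATG-initiated by default (a stop-free-
segment mode is available) because the assembler-style "longest 6-frame"
rule is not published in detail; the choice is pinned and configurable.
Ks histograms use 0.01 bins; the reported peak is given both as the
histogram mode and as the mode of a Gaussian KDE, because the mode of a
0.01-binned histogram over ~150 gene-level Ks values (per-gene SD ≈ 0.04
at Ks 0.27) jitters by several bins while the KDE mode is stable.

## Pipeline report and scoring

Each stage logs in/out counts with per-reason discards; reasons partition
the discards exactly. When the run starts from the simulator, the report
scores: topology recovery (clusters with a definite category vs the
category implied by the true fate, excluding identical-parent genes, whose
category is undefined), origin accuracy (confirmed calls vs the true
subgenome of the contig's reads), and differential-expression calls vs the
truth flags. On the default 500-gene conditions the pipeline classifies
~150 clusters with ≥ 94% topology recovery and ≥ 98% origin accuracy; the
main loss channel is dual-copy genes whose second homeolog drops below the
3-read contig floor and which are then classified as single-copy.

## Known limitations

* Single-linkage clustering reproduces threshold *phenomena*, not
  assembler-specific contig structure; chimeric consensus can only arise
  transiently before phasing, and the phasing split assumes exactly two
  haplotypes.
* The bootstrap clamp at p = 0.7499 slightly compresses replicate
  distances for near-saturated pairs.
* NG86 is a counting estimator: no transition/transversion bias, no codon
  frequencies, no likelihood models of selection; its bias grows with
  divergence and is documented, not corrected.
* Homeolog-pair statistics at default fate probabilities rest on few
  (~10) surviving dual-copy clusters, so their correlations are noisy by
  construction.
* The expression model has no biological replicate variance; differential
  calls are tested against Poisson sampling only.
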