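# Methods

This note records the models, parameter choices and numerical conventions
behind `panmosaic`, and what the synthetic panel does and does not emulate.

## The synthetic panel

The simulator produces the study design the analysis chain targets: a small
panel of inbred-like lines from two germplasm groups ("flint"-like, four
lines; "dent"-like, two), whose genomes differ by substitutions, mobile
element insertions, satellite arrays, gene gains and recent shared
haplotypes.

**Phylogeny and substitutions.** Lines sit on a fixed rooted tree
(((fl1,fl2),(fl3,fl4)),(dt1,dt2)) with branch lengths in expected
substitutions/site: terminals 1.5×10⁻³, internal branches and clade stems
2×10⁻⁴. Substitutions are uniform across sites with equal exchangeabilities
(Jukes–Cantor-like); per-branch counts are Poisson(L·rate·length).
Downstream methods consume only identity fractions, so substitution-model
detail is irrelevant. The terminal-heavy shape keeps the SNP-level identity
of every line pair in the 0.64–0.70 band, for two reasons: (i) it puts the
null maximal run of identical SNP calls between unrelated haplotypes in the
low-to-high 20s for the realized site counts — comfortably below the
40-site haplotype seed, which is the regime the seed threshold is built
for; (ii) it keeps within-clade junction flanks similar enough (≤0.5%
diverged) that shared TE insertions cluster at the 98% junction threshold.

**Insertions.** All insertion events are planted at ancestral coordinates
drawn to be mutually non-nested (margin 1.5 kb) and outside IBD tracts, so
every line's coordinate map to the ancestor stays strictly monotone and
tract splices stay length-preserving. Events are applied at the end of
their branch; an inserted element therefore accumulates substitutions only
on the branches below it.

* *LTR elements*: two identical terminal repeats (250–700 bp) around a
  random internal region (4–9 kb), with a domain-order label drawn as
  RLG (60%), RLC (30%) or RLX (10%), and a 4–6-bp target-site duplication
  (the detection window tolerates 4–20 bp; 4–6 is the common biological
  range). A share of elements (default 40) predate the panel split and are
  built into the ancestor with a planted 5′/3′ LTR divergence drawn
  uniformly from 0–2%, giving the panel an age spectrum up to ≈770 kyr at
  the default clock. Each event gets its own element sequence; family
  structure is not modelled, which keeps junction truth unambiguous.
* *Knob arrays*: exact tandem stacks of a 180-bp or 202-bp monomer
  (synthetic stand-in consensi shipped in code; real consensus sequences
  can be supplied), unit counts log-uniform on [1, 500], then mutated like
  ordinary sequence. Knob events keep a 1.2-kb clearance to genes, so the
  panel reproduces a gene-free perimeter around satellite arrays.
* *Genes*: 240 ancestral genes (0.9–2.4 kb) plus per-branch gains
  (Poisson(5)); 60% of gains are tandem duplications placed directly
  downstream of an ancestral gene and tagged with its tandem group, which
  by construction enriches line-specific genes for tandem duplicates.

**IBD tracts.** After the tree walk, each configured tract (default: 20
tracts of 100–400 kb, disjoint, spread over within-clade, cross-clade and
higher-order subsets including one flint-clade-wide tract) is realised by
copying one carrier's evolved segment onto the others at orthologous
coordinates, then applying a small post-copy substitution rate per carrier
(10⁻⁵/bp). The post-copy rate keeps in-tract SNP-call identity ≥99% even
in the worst case (a clade-wide tract, where only the other clade's
variation remains segregating and the relative weight of post-copy noise
is largest) — real IBD is near-identical, not byte-identical, and this is
the regime the 98% extension threshold assumes.

**Not emulated:** recombination/coalescent structure (tracts are planted,
not generated by a genealogical process), indels outside planted events,
rate heterogeneity, nested or truncated (solo-LTR) elements, segmental
duplications, and sequencing/assembly error. Passing recovery tests
therefore demonstrates correctness of the block/run/cluster machinery
under clean substitution-dominated divergence, not robustness to assembly
artefacts or repeat-induced alignment ambiguity at chromosome scale.

## Alignment blocks

The internal aligner indexes genome-wide unique 20-mers, intersects the
two genomes' anchor sets, and chains anchors along common diagonals (gap
≤5 kb), extending block ends by exact matches. Blocks are gapless by
construction, which is exact for the simulator's substitution-only
divergence and a deliberate restriction otherwise; chromosome-scale or
indel-rich data enters through `read_coords` (MUMmer `show-coords`,
1-based inclusive converted to 0-based half-open at the boundary).
Alignments shorter than 250 bp are dropped at this stage. Reverse-strand
homology is detected through a second anchor index on the
reverse-complemented query; panel pipelines disable that pass by default
because the simulator plants no inversions (minus-strand handling is
exercised by the unit tests and available via ``both_strands=True``).

Best one-to-one selection admits blocks by descending score
(identity×length, mirroring a weighted-length filter). A candidate
overlapped at an end by retained blocks is trimmed — the trim is applied
equally on both coordinates, exact for gapless blocks and a proportional
approximation for imported gapped alignments — while a candidate
overlapped in its middle, or left shorter than 500 bp, is removed.
Interchromosomal candidates must reach 99% identity with end overlaps
≤10 bp. "Adjacent" for that test means the nearest retained block on each
side in reference coordinates. MAB chaining treats adjacency as rank
adjacency in both genomes (any gap size), with consistent orientation.

Coverage projection counts each partner line at most once per base and
excludes interchromosomal blocks by default (they predominantly reflect
paralogy). Label precedence per base: unaligned (no partner), else
group-specific (all own-clade partners, no other-clade partner), else core
(≥ core_k partners, default 4), else other. With the default group sizes
the first three conditions are mutually exclusive.

## Core blocks and SNPs

Reference core intervals are merged when touching, then *split at every
partner SAB boundary*; a segment covered one-to-one in every line becomes
a complete core block (segments under 200 bp are discarded, and leftovers
are kept as partial and excluded from SNP calling). Without the split,
almost every merged core interval would contain some single-partner
alignment gap and be demoted whole; with it, completeness is decided at
the finest unambiguous resolution.

Block MSAs take the trivial columnwise alignment when all rows have equal
length (always true for the internal gapless blocks); otherwise a
centre-star progressive alignment around the reference row uses affine-gap
Needleman–Wunsch (match +1, mismatch −1, gap open −4, extend −1) merged
under "once a gap, always a gap". Columns containing any gap are skipped;
multi-allelic columns are retained. Each emitted site carries one
orientation-adjusted coordinate per line, so alleles round-trip exactly to
the genomes.

## Runs of identity

The pairwise detector is defined exactly: a *run candidate* is a maximal
site-index segment that (a) contains at least `seed_min` (40) consecutive
identical calls and (b) has identical-call fraction ≥ `min_identity`
(98%, compared in exact integer arithmetic). Enumeration uses the linear
transform Q[x] = den·P[x] − num·x (P the prefix count of identical
calls): a segment [i,j) is valid iff Q[j] ≥ Q[i], so maximal segments
correspond to prefix-minimum records of Q matched against suffix-maximum
records, subject to the seed-coverage constraint. This is exact and
O(n log n); the test suite verifies set equality against an independent
brute-force oracle.

Maximal ≥98% segments necessarily carry sub-threshold extension tails: a
run of m sites at internal identity q can extend ≈ (q−θ)/(θ−p)·m sites
into background with pairwise identity p before the overall fraction
falls below θ = 0.98 — at p≈0.65 roughly 5–10% span inflation per side,
pure noise relative to the underlying shared haplotype. Reported runs
therefore merge overlapping maximal segments and trim the extent to the
outermost fully identical ≥40-site windows (`trim_to_seeds=False` and
`merge=False` expose the raw enumeration). Runs never cross core-block
boundaries, and a run's genomic span per line is the distance from its
first to its last member site.

Higher-order haplotypes re-express each site as a 15-bit vector of
pairwise *run membership* (not per-site allele identity — the bits encode
the detected runs-of-identity). Within a block, maximal stretches of a
constant nonzero pattern are linked across gaps of at most 2 nonmatching
sites, and a linked group is reported when some member stretch reaches 40
sites. Bridged sites count toward the genomic extent but not toward
`n_sites` or identity accounting; membership (for the no-overlap
guarantee) is defined by matching sites only.

The null calibration simulates i.i.d. Bernoulli(p) site identity and
records the maximal success run per replicate, alongside the Erdős–Rényi
asymptotic log₁/ₚ(n(1−p)). At the panel's realized p and n the expected
null maximum is in the 20s, which is why a 40-site seed is effectively
free of false positives (measured rate < 10⁻³ per 10⁶ sites at p = 0.5).

## fl-LTR synteny and ages

Candidate elements enter from annotation (GFF3 with `ltr5`/`ltr3`/`domains`
attributes) or from the simulator's truth; full de-novo detection is out of
scope since the analysis of interest is downstream of it (a naive
direct-repeat scanner with a target-site-duplication check,
`detect_fl_ltr_naive`, is provided for toy genomes only). Filtering
requires ≥1 canonical domain (GAG/PR/INT/RT/RH) and tandem content <25%.
Superfamily assignment follows internal domain order (RT–RH–INT → RLG,
INT–RT–RH → RLC); elements missing or duplicating INT or RT are RLX.

Ages use T = d/(2μ) with μ = 1.3×10⁻⁸ per site per year and d the raw
substitution fraction over aligned columns of a global 5′/3′ LTR alignment
(equal-length pairs compared columnwise; otherwise edlib's edit-distance
path). A Kimura two-parameter correction is available behind a flag but
raw proportion is the default. Pairs aligning below 70% identity are
flagged unreliable rather than dropped.

Junction signatures are 100 bp (50 inside + 50 outside each element end);
elements within 50 bp of a contig end are skipped with a logged reason.
Clustering is greedy against centroids in deterministic order (length,
then id), joining at ≥98% identity and ≥98% mutual coverage — a
reproducible stand-in for dbcluster-style clustering. Two elements share
a syntenic location iff *both* junction pairs co-cluster (an
either-junction mode exists behind a flag); with both junctions required,
location groups are exactly the (upstream, downstream) cluster pairs, so
transitive closure is automatic, and a line contributing two elements to
one location marks the record ambiguous. Pan/core curves average over all
orderings (720 at six lines) and the sharing matrix is the asymmetric
fraction of the row line's locations present in the column line, with an
average-linkage display order.

## Repeats, knobs, neighbourhoods

The scanner seeds on exact 12-mers, evaluates one gapless candidate window
per (element, strand, diagonal), and trims it to the best-scoring
sub-segment (+1 match / −2 mismatch) before applying the identity (≥70%)
and length (≥75 bp) thresholds — appropriate for the substitution-only
divergence the package simulates. Overlap resolution admits hits by
descending identity×length; a lower-scoring hit overlapped <90% is
shortened to its uncovered remainder(s), each of which must keep ≥50 bp (a
middle overlap may split a hit in two — the rule is applied to every
remainder), otherwise removed. The output provably contains no overlapping
bases, and the highest-scoring hit is never trimmed.

Knob arrays chain same-monomer hits separated by ≤50 bp (a configurable
merging distance); one isolated monomer is a legitimate cryptic site with
unit count 1. Gene neighbourhoods report the strand-aware distance from
each gene's 5′ end to the nearest annotated element edge per class (0 for
genes overlapping an element, a none-sentinel when the contig has no
element of that class), optionally joined with max-over-conditions TPM.

## Pan-genes

Similarity scores are an input; on the synthetic panel they are generated
from the actual sequence identity of planted gene copies
(identity × min length over each homology group), which exercises the
orthology machinery without an external aligner. RBH pairs are mutual
unique bests per line pair, ties broken toward the lexicographically
smaller id and flagged. Clusters are connected components of the RBH graph
restricted to collinear edges (same chromosome name, gene-rank offset ≤10
— an explicit stand-in for a full positional consolidation); cluster size
counts distinct lines, so co-orthologous extra copies do not inflate it.
Labels: core = all lines, singleton = one line, dispensable = in between.
The tandem enrichment is a two-sided Fisher exact test (scipy), verified
in the tests against full hypergeometric enumeration.

## Problem sizes and determinism

The default panel is 6 lines × 2 chromosomes × 5 Mb with 20 IBD tracts
(100–400 kb), ~160 branch TE events, 40 ancestral elements, 8 knob arrays
and ~1,540 genes; it yields ~90k orthologous SNP sites and runs through
the full pipeline in about two minutes on one CPU. Unit tests use a 1-Mb
panel; the substitution-only SNP-recovery panel is 4 Mb. All randomness
flows through numpy Generators seeded from explicit configuration; greedy
orders (clustering, overlap resolution, SAB selection) are fully
deterministic, so identical seeds reproduce identical outputs.

## Known limitations

* The internal aligner assumes collinear, inversion/indel-free homology
  within a block; structural-variant typing is explicitly out of scope.
* Sharing requires intact elements in both lines; relic (junction-only)
  sharing is off by default, so element loss after insertion is read as
  absence.
* The identity×length score stands in for aligner-specific scores in both
  SAB selection and repeat priority; rankings can differ from external
  tools near ties.
* Greedy centroid junction clustering can split a location when carriers
  straddle the identity threshold around different centroids; accuracy is
  ≥95% on the default panel but degrades as flank divergence approaches
  2% per pair.
* PAV accuracy depends on the provided score table; with real BLAST scores
  the rank-offset constraint (default 10) becomes the binding parameter.
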