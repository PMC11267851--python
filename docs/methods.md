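# Methods

## The model

A growing tree is represented by a rooted topology whose tips are the
sampled branches.  Each meristem node carries two quasi-independent stem
cell layers, L1 and L2.  Somatic mutations arise per node and layer and
are inherited by every branch developing below that node, in the same
layer; a mutation's *branch set* is therefore the complete tip set of its
origin node (a clade).  Three further mutation classes complete the
picture: *pre-graft* mutations fixed in the cutting the tree was grafted
from (present in all branches), *layer-shared* mutations reflecting rare
cellular exchange between layers, and *organ* mutations that arose during
the development of a single fruit or leaf and are private to one sample.

Tissue samples are cell mixtures.  A heterozygous mutation carried by a
fraction *f* of a sample's cells has expected alternate allele frequency
AF = f/2.  Default mixture proportions: fruit peel 95% L1 / 5% L2, fruit
flesh 2% L1 / 98% L2, bulk leaf 8.9% L1, 78.2% L2, 7.2% L3 and 5.7%
unassigned — the leaf values are the cell-type proportions observed by
single-cell expression profiling of this system.  These defaults are why
an L1-specific mutation is practically invisible in bulk leaf data
(expected AF ≈ 0.0445, ≈13 of 300 reads, below the 20-read/0.25-AF calling
threshold) while an L2 mutation is easily called (AF ≈ 0.39).

## Synthetic data

The simulator emits allelic count tables in the bam-readcount text
dialect at truth-mutation positions plus background positions on a
synthetic genome (default two chromosomes × 1 Mb, with AT-dinucleotide
microsatellite hotspots where most indels are placed as 2-bp slips).
Sequencing noise: per-site depth is negative-binomial around the sample
mean (default 300×, matching the 198–422× study range; dispersion r = 10),
alternate reads are binomial with a per-base error rate of 10⁻³ split
evenly over the three non-reference bases, and strand counts split 50/50.
A fraction of background sites (4% + 4%) receives repeat-like (3×) or
dropout (0.25×) coverage, consistent across samples — these loci are what
the per-sample optimal depth range is meant to exclude, and truth
mutations are placed at normal-coverage (callable) loci.  Mutation-rate
defaults are 4 (L1) and 2 (L2) mutations per topology node — the 2:1
ratio is the study condition for the layer-load contrast; absolute
per-node rates are free parameters, not estimates — with 21 pre-graft L1
and 1 pre-graft L2 mutations, a 6% layer-shared fraction (half placed at a
single random branch, half at the root, mirroring the observation that
half of the layer-shared mutations sat at one branch), one organ mutation
per leaf, and a 56% indel fraction with 70% AT-slips.  SNVs are drawn with
a 60% transition bias.

For LOH, the simulator produces read-level haplotype observations at
adjacent phased variants: event-free pairs draw a parental haplotype per
read (mis-assignment at the error rate only), pairs spanning a planted
tract boundary switch haplotype, and allele frequencies inside the tract
collapse toward the retained haplotype scaled by the carrier layer's
purity.  Single-cell counts give each barcode one read per covered site:
cells of the origin layer are mutant with probability 0.5 (heterozygous
expression), other layers only via an optional contamination rate; an
exact mode plants fixed mutant-cell counts per layer for round-trip tests.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: alignment and mapping artefacts, index
hopping and sample cross-contamination, GC- or mappability-dependent
coverage, sequencing-error motifs, UMI structure in single-cell data, and
any linkage between neighbouring mutations.  Real-data dropout is the main
reason published genotyping-sweep support (~80% of L1 mutations at 1–2
reads in leaves) is lower than the near-100% this binomial model yields.

## Calling thresholds

All thresholds live in one validated record (`FilterConfig`): candidate
sites need ≥3 alternate reads; confident calls 20 reads; heterozygous
background is AF 0.3–0.65; layer contrast needs an AF difference ≥0.25
(pipeline 1) or |log2 fold-change| ≥1 between layer-mean AFs (pipelines
2–3; the fold-change floor is a package default, with a depth-aware
pseudo-AF of half a read at the site's mean depth guarding zero
denominators).  Noise proxies replace visual inspection: single-strand
alternate support, mean base quality of the alternate allele below 30, or
depth above 500 (repeat-like).  Multi-allelic candidate sites keep the
highest-count alternate and are flagged.

Two thresholds deserve explanation:

* **Optimal depth range.**  Formalised as the 0.05/0.95 quantiles of each
  sample's non-zero depth distribution (the published ranges were picked
  per sample off depth histograms; quantiles are the reproducible
  stand-in), with per-sample manual overrides available.  In pipelines 2
  and 3 a branch whose coverage is out of range at a site is treated as
  not supporting the site, rather than vetoing the site for all branches.
* **The 99th-percentile AF-difference rule** (pipeline 1).  The threshold
  adapts to each branch's technical AF scatter.  It is computed over the
  *sub-threshold* background — sites surviving the het/depth filters whose
  AF difference is below 0.25 — because on data where true mutations are
  not a vanishing fraction of all sites, a percentile taken over a
  distribution that includes the mutations themselves would reject them.

The merge step collapses duplicate calls across pipelines, resolves layer
labels (a specific L1/L2 label from the layer-aware pipelines overrides
the layer-agnostic pipeline's "shared"; genuinely conflicting L1-vs-L2
labels become "shared" with a warning and a flag) and re-genotypes every
call in every sample at relaxed thresholds (≥5 alternate reads and AF
≥0.1).  Presence in the final catalog — the per-call sample list and the
branch set — is exactly the set of samples passing this evidence re-check,
with provenance recorded for presences the pipelines themselves did not
call.  This is the computable replacement for the study's manual
re-checking of all samples at called positions; no call is silently
dropped.

## LOH

A call requires both signals in the same branch and layer: phased het
sites whose AF leaves the het band (0.35–0.6) in exactly one layer with
|ΔAF| ≥ 0.25 and adequate depth (≥ the sample's range floor — "few reads"
formalised through the sample's own depth model), and ≥10
haplotype-switch reads between phased sites ≤1 kb apart, absent from the
other layer.  Switch regions mark tract *edges* while the AF shift covers
the interior, so consecutive switch regions bracketing AF-shift candidates
are merged into a single tract and yield one call anchored at the first
shifted locus.

## Spectra and enrichment

SNVs are reported in canonical pyrimidine-centred form (purine-centred
changes reverse-complemented); the CpG flag marks C>T at CG dinucleotides.
Indel sizes are signed (negative deletions).  Region enrichment assigns
each call one class by the priority CDS > UTR > intron > TE > repeat >
intergenic (the published classes are disjoint but the assignment rule is
unstated), builds a 2×2 table of mutations in/out of the class against
callable bases in/out, applies a one-tailed Fisher exact test (default
tails: depletion for genic classes, excess for TE/repeat/intergenic) and
adjusts with Benjamini–Hochberg across classes, the field default where
only "adjusted" is stated.  Callable lengths are an input, not recomputed,
since they depend on per-sample depth masks.

## Tree analysis

Distances between samples are unweighted Hamming counts on the binary
presence matrix — the simplest choice consistent with unrooted
neighbour-joining input.  NJ is implemented in the package (Saitou–Nei
with deterministic lowest-index tie-breaking, exact on additive matrices
including edge lengths; negative estimates are kept so additivity is
preserved) because determinism and exactness are part of its contract
here; the scikit-bio implementation serves as an independent cross-check
in the tests, never as the implementation.  The layer-versus-branch
statistic is the mean distance between same-layer samples of different
branches minus the mean distance between different-layer samples of the
same branch; its null shuffles layer labels within each branch.  With only
two samples per branch that group has 2⁷ elements and a global label-swap
symmetry capping attainable p-values near 0.016, so the bundled analyses
include the bulk-leaf samples as a third tissue class, which is both
biologically meaningful (leaves track L2) and gives the test resolution.
Tree-wide fixed mutations can be excluded by restricting the catalog to a
subtree before computing distances.

## Genotyping

Bulk sweeps declare a mutation present in a sample at cutoff *k* iff the
site has ≥*k* alternate reads (absent sites count as zero); joint sample
sets require support in every member, querying only branches where the
mutation was originally identified.  Support percentages are monotone
non-increasing in the cutoff by construction.  In single-cell data a cell
is mutant with ≥1 mutant-allele read — matching binary per-cell colouring
and the low coverage of scRNA libraries, with no UMI-depth threshold —
and cluster tallies sum to the number of covered cells.  Barcodes missing
from the cluster map are dropped with a warning; sites with no covered
cell are reported as uncovered rather than omitted.  Sites whose mutant
reads concentrate suspiciously are flagged, not removed.

## Problem sizes and determinism

The bundled analyses run on a 2 Mb synthetic genome with 4,000–5,000
background sites per sample, 21 samples at 300×, 10 simulation seeds for
recovery statistics, 20 for the LOH null, 200 replicates for enrichment
calibration, 50 random additive matrices (6–14 taxa) for NJ, and 3,000
permutations for the clustering test — sizes at which every quantity is
stable while the whole analysis reruns in minutes.  All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
seeds give byte-identical emitted fixtures and reports.

## Known limitations

Structural variants, transposon insertions and meiotic-recombination-like
events are out of scope (the source study found none of the latter), as is
the classification of complex multi-allele events.  The leaf "library or
sequencing bias" filter is operationalised as the strand/quality proxies
above and may differ from the original manual criteria.  Depth ranges are
not GC- or mappability-corrected.  The simulator's idealised noise model
overstates genotyping sensitivity at 1–2 read cutoffs relative to real
libraries (see above).
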