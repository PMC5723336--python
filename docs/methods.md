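# Methods

This note documents the models and procedures implemented in placeprof, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic benchmarks do and do not demonstrate.

## Recruitment

Reads are translated in all six frames (translation table 11; codons
containing ambiguities become `X`, stop codons `*`, trailing partial codons
are dropped) and compared to the ungapped reference proteins by exhaustive
affine-gap Smith–Waterman. No seeding heuristic is used: reference sets are
tens to low hundreds of sequences, so exactness is affordable and makes the
engine directly checkable against a brute-force dynamic program. The DP
kernel is numba-compiled and batches reads so the inner loop vectorizes
across queries; query padding uses a sentinel residue that scores −1 against
everything, which can only shorten an optimal local alignment and therefore
never changes a score.

Significance uses Karlin–Altschul statistics, `E = K·m·n·e^(−λS)`, with `m`
the translated query length and `n` the total database residues. Defaults
`λ = 0.267`, `K = 0.041` are the standard gapped BLOSUM62 (gap open 11,
extend 1) calibration; both are fields of `ScoringScheme` and can be
overridden, e.g. when changing the matrix or gap costs. The recruitment
threshold is `E < 1e-5`; a stricter `E < 1e-60` (used in reference-package
candidate screening for full-length sequences) is just a different value of
the same flag.

Per read, the best (frame, reference) pair is chosen by lowest e-value,
ties broken by higher score, then by frame order +1, +2, +3, −1, −2, −3 —
a fixed rule so results are reproducible. The recruited amino-acid sequence
is the locally aligned query interval: local alignment against the
reference automatically trims overhang beyond the gene's extent. Stops and
ambiguities inside the interval are masked to `X` rather than deleted,
preserving column registration for the placement step. Reads shorter than
`min_aa = 33` aligned residues (≈100 bp of coding sequence) are dropped;
the filter applies per mate, before pair combination.

A minimal overlap-merge utility for read pairs is provided
(`merge_overlapping_pair`: maximal suffix/prefix overlap above a length and
identity threshold, mismatches resolved by base quality). Upstream quality
control, adapter trimming, digital normalization, and assembly are out of
scope.

## Reference packages

A package bundles the aligned full-length references (exactly identical
amino-acid sequences de-duplicated, first occurrence kept), the reference
tree with deterministic postorder edge ids, clade (phylotype) labels, the
outgroup leaf set, and the model settings. Clades and the outgroup must be
monophyletic and mutually disjoint; violations are hard errors naming the
offending leaves. Clade boundaries are user input: the package validates
them but does not infer them.

The gene length in the normalization equation is taken as the **median
ungapped amino-acid length of the ingroup references** — robust both to
fragmentary references and to alignment padding (all-gap columns provably
do not change it).

Each clade's edge set is the edges strictly inside its MRCA's subtree
**plus the MRCA's stem edge** (configurable): a query diverging just below
a clade's ancestor is biologically that lineage. Remaining ingroup edges
are labeled `unassigned_ingroup`; they count toward gene totals but toward
no named clade.

## Substitution model and likelihood

The placement model is a reversible amino-acid CTMC: a named
exchangeability matrix (LG default; WAG, JTT shipped as plain-text data in
the conventional lower-triangle layout) combined with matrix-supplied or
empirical (alignment-counted, +1 pseudocount) stationary frequencies, with
the rate matrix normalized to one expected substitution per unit branch
length. Rate heterogeneity uses the discrete-gamma approximation with
`k = 4` equal-weight categories and shape `α = 1.0` by default (both
configurable); category rates are the exact means within quantile bins,
computed from the regularized incomplete gamma function, so the mean rate
is exactly 1. Model selection per tree is deliberately replaced by explicit
configuration.

Tree likelihoods use Felsenstein pruning with gaps as missing data
(all-ones conditionals), per-(category, site) rescaling against the running
maximum with log accumulation, and transition matrices from a symmetrized
eigendecomposition cached per model. Likelihood is invariant to the Newick
rooting (the root is kept only for traversal bookkeeping).

## Placement

For each reference package the engine precomputes, once, the "down"
(subtree) and "outside" partial likelihoods for every edge, then scores a
query on edge *e* as the likelihood of the tree with the query attached at
the **midpoint** of *e* through a pendant branch:

* phase 1 scores every edge with pendant length fixed at 0.1
  substitutions/site;
* phase 2 re-optimizes the pendant length by golden-section search on
  [1e-8, 2.0] to tolerance 1e-4, on the top `max(5, ⌈10 % of edges⌉)`
  candidate edges (breadth configurable).

Only the pendant is optimized — the one-dimensional search keeps placement
fast and deterministic; the proximal/distal split is not re-optimized, a
documented simplification of the full three-branch-length refinement.
Likelihood weight ratios normalize the per-edge likelihoods over **all**
edges (all are evaluated in phase 1). Ties in the best edge break toward
the smaller edge id. Per-edge placement log-likelihoods are exact: they
equal brute-force enumeration over internal-node states to ~1e-15 relative
(enforced by the test suite at 1e-10).

Recruited reads are registered to the reference columns by a
global-in-read / local-in-profile affine alignment against per-column
BLOSUM62 profile scores (frequencies diluted by gaps, so sparse columns
score weakly; skipping a column costs gap penalties scaled by column
occupancy, making all-gap columns free). Read residues that fall between
reference columns are dropped — reference columns are never modified. Mate
pairs are combined into **one** query before placement: union of coverage,
agreeing residues kept, disagreements masked to `X`.

## Quantification

A placement is discarded iff its best edge lies in the outgroup edge set —
essential where the outgroup is a close homolog (nitrate reductase *narG*
vs nitrite oxidoreductase subunit *nxrA*, and *nxrB* vs *narH*). Kept
placements are tallied per clade; "reads" in the normalization equation
means placed queries, so a combined mate pair counts once (a summed-residue
alternative would weight long overlaps differently; counting queries is the
default and recorded in output). Per-sample normalization only: a sample's
gene counts are divided by the same sample's *rpoB* placements. When a
sample has no *rpoB* placements the percent is emitted as an explicit
undefined marker (`NA`), never as zero.

Copy-number correction divides a clade's percent by its known copies per
genome (TSV input: gene, clade, copies) before totals are re-summed.
Particle vs free-living enrichment is reported as
`log2((p + 0.1) / (f + 0.1))` at matched depths; the 0.1 pseudo-count keeps
zero-vs-zero at exactly 0. This ratio is a convenience metric layered on
the per-fraction percent columns, which remain the primary output.
Absolute cell densities are out of scope: the percent is relative to the
prokaryotic community at each depth.

## Synthetic benchmarks

The generator (`placeprof.synth`) emulates the statistical structure the
quantification assumes: a community of genomes with known relative
abundances, each carrying single-copy *rpoB*; marker genes present in a
configurable subset of genomes at configurable copy number, with phylotypes
drawn from distinct reference-tree clades; an optional outgroup-contaminant
fraction per gene; and uniform-random background DNA exercising recruitment
specificity.

Reference alignments are simulated along the reference tree under the
placement model itself (root from the stationary distribution, one gamma
category per site); genome-resident gene copies are the source leaf evolved
a further 0.03 substitutions/site, so simulated reads are near — not
identical to — a reference. Read pairs (150 bp, insert 260 ± 25 bp by
default, matching short-insert Illumina libraries) carry substitution
errors at rate 0.002/bp by default; an indel mode exists to stress frame
trimming. Fragments are drawn from gene copies with probability
proportional to abundance × copies × gene length, with starts uniform among
positions where the insert fits; synthetic marker genes and *rpoB* share
the same length (300 aa), so fragment-position edge effects cancel exactly
in the percent ratio. Every pair is recorded in a truth table.

Benchmark scenarios are small by design (≤ a few thousand read pairs, two
clades of three leaves plus a three-leaf outgroup per gene, 300-aa genes)
so the full suite runs in minutes; these sizes are a deliberate
desk-scale choice and all recovery statistics are judged against binomial
envelopes at the realized counts, not point values.

**What passing benchmarks do not show about real data:** synthetic
references are simulated under the same model used for placement, so the
benchmarks cannot detect model misspecification (real protein families
violate site-independence and have heterogeneous composition); background
DNA is uniform-random, a much easier rejection problem than real homologous
bystander genes; reference trees here are small and well-separated, whereas
real marker phylogenies contain short internal branches where placement
uncertainty (spread LWRs) matters; and sequencing error is substitution-only
by default. The benchmarks validate the machinery — recruitment thresholds,
frame trimming, pair combination, placement likelihoods, outgroup
filtering, and the normalization arithmetic — not the biology of any
particular reference package.

## Numerical and design notes

* Edge ids are assigned by deterministic postorder (children in written
  order), making numbering a pure function of the Newick string; jplace
  output carries `{edge_id}` annotations.
* De-duplication keeps the first occurrence as representative; the mapping
  is emitted so clade/outgroup membership survives collapsing.
* Underflow is handled by per-(category, site) rescaling; no site
  likelihood can reach zero since transition matrices are strictly positive
  for positive branch lengths.
* All tie-breaks (traceback direction, equal-scoring alignment end cells,
  best frame, best edge) are fixed and documented, so identical inputs give
  byte-identical outputs; the pipeline's determinism is asserted at file
  level in the test suite.
* Per-sample failures (unreadable FASTQ, malformed records) are isolated:
  the run continues, the failure is recorded in `run_log.yaml`.
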