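# Methods

`tescout` re-implements, as a reusable and fully testable pipeline, the
computational procedures used to evaluate long-terminal-repeat (LTR)
transposable elements (TEs) as candidate enhancers in mouse embryonic (ESC)
and trophoblast (TSC) stem cells: element classification from epigenomic
peak sets, mappability and peak-recoverability simulation, repeat-family
sgRNA panel design for CRISPR interference, promoter capture Hi-C (PCHi-C)
gene linking, allele-specific enhancer calling, and H3K27ac effect
quantification. A synthetic-data generator provides fully labelled inputs
with the statistical structure each stage assumes, so every claim the test
suite makes is checked against planted ground truth rather than downloads.

## Coordinates and overlap

All coordinates are 0-based, half-open, everywhere. BED input is native;
RepeatMasker `.out` rows (1-based inclusive starts) are converted on read.
"Overlap" means at least one shared base unless an operation states a larger
minimum — abutting half-open intervals share nothing. All overlap logic is
strand-blind; strand is stored for provirus calling and read simulation
only. `overlap()` is a per-chromosome sorted sweep whose output is checked
against a quadratic all-pairs oracle in the tests.

## Element classification

A TE copy is called a **TE+ enhancer** when it satisfies, conjunctively:

* no H3K4me3 peak overlap and a TSS distance strictly greater than 500 bp
  (edge-to-point), ruling out promoters;
* overlap with an H3K27ac peak AND an ATAC peak AND at least one binding
  peak among the lineage's key transcription factors (OCT4/SOX2/NANOG in
  ESCs; CDX2/ELF5/EOMES in TSCs).

**TE− enhancers** are ATAC peak regions overlapping no annotated repeat
(a single shared base disqualifies) passed through the identical filters.
**Non-enhancer TEs** are the matched control set: copies with mappability
score strictly above 0.5, not already TE+, ranked by ascending ATAC signal
and taken to twice the TE+ count of the same family (ties broken by copy
id). Peaks of the three assays are each required to touch the element
independently; mutual overlap among the peaks is not required. Elements
failing classification and not selected as controls stay `unclassified` and
are excluded from group comparisons.

## Mappability

The mappability score of an element is the fraction of its length covered
by at least one read whose sequence occurs exactly once in the genome
across both strands. Reads of length 40 (configurable, minimum 20) tile
every start position within the element (stride 1, the most conservative
choice); uniqueness is exact-match, implemented by canonical k-mer counting
(a locus carrying k-mer *w* on the forward strand carries its reverse
complement at the same place, so multiplicity across both strands equals
the canonical-form count). The retention rule is strict: score > 0.5.

## Solo LTR versus provirus

Two consecutive same-subfamily copies on the same strand whose gap lies in
[1 kb, 15 kb] are labelled `proviral_pair`; the same configuration with
discordant strands is `ambiguous`; everything else is `solo`. The window
reflects typical murine ERV internal-region sizes (~5–10 kb); all three
parameters are configurable and should be treated as placeholders when the
qualitative arrangement criterion matters.

## ChIP-seq simulation and recoverability

Per element, fragments of length 150 ± uniform jitter of 40 are centred on
the element midpoint and a 40-bp read is sequenced from a uniformly chosen
fragment end; uniform background reads cover a 10-kb window around the
element (`background_depth`, default equal to the peak depth of 200
fragments per element, keeps the read-count identity exact). Mapping is the
same exact-uniqueness contract as mappability scoring. The peak caller is a
deliberately simple Poisson model: a base is enriched when its count beats
a Bonferroni-corrected upper-tail Poisson test (alpha = 0.05 over the
genome length); enriched runs separated by fewer than `merge_gap`
non-enriched bases are joined (the fragment-end read model leaves a dip at
the element midpoint — fragment 150 ± 40 with 40-bp reads covers roughly
[mid−95, mid−15) and [mid+15, mid+95) — and peak callers routinely merge
nearby enriched windows), and runs at least 100 bp wide become peaks.
`merge_gap` defaults to 0 in the caller itself; `recoverability()` passes
2 × read length. An element is *recovered* when a called peak overlaps it;
calling on pre-mapping coverage (all reads kept) recovers every element and
serves as the control, while verbatim-duplicated elements fail post-mapping.

## Guide design

Candidate protospacers are every 20-mer immediately 5′ of an NGG PAM on
either strand of any target copy, merged by sequence with unioned hit
lists. Panel selection is greedy, matching the family-targeting heuristic
the design emulates: the *breadth* objective adds the guide covering the
most yet-uncovered copies (ties: larger total hit count, then lexicographic
protospacer — making panels order-independent); the *depth* objective adds
the guide maximising the number of copies reached by ≥ `min_depth`
(default k) selected guides, with total depth as tie-break. Greedy maximum
coverage guarantees only (1 − 1/e) of the optimum in general; the test
fixtures therefore come in two families: structured instances whose
optimum is provably greedily reachable (disjoint primary guides plus
subset guides; two stacked guide groups of distinct set sizes), used to
check counting and tie-breaking against an exhaustive C(n, k) oracle, and
unstructured random instances, used to check the approximation bound.
Off-target scanning is a Hamming-distance search under the PAM constraint
(mismatches ≤ 5), vectorised but verified against a position-by-position
oracle. "Predicted to be targeted" uses 0 mismatches by default.

## Gene linking and expression

Elements are assigned to the non-promoter restriction fragments they
overlap and inherit the genes of every promoter fragment those fragments
interact with; an element overlapping only promoter fragments gets no link
(flagged). Genes linked to both TE+ and TE− enhancers are excluded before
any expression comparison; the partition is checked for disjointness and
conservation. Histogram matching maps each sample's ranks onto the
reference's empirical distribution by quantile interpolation — idempotent,
rank-preserving, and exact when lengths agree; constant samples map to the
reference median with a warning. Lineage ratios are
log2((mean_ESC + 1)/(mean_TSC + 1)) restricted to genes with mean
expression ≥ 1 (FPKM-like) in at least one lineage. Pseudocount 1 is used
for every ratio in the package.

## Allelic analysis

A peak is allele-specific when one allele carries at least 5 reads and the
allelic ratio (129 reads / total) is strictly above 0.8 or strictly below
0.2; selected peaks intersected with the TE annotation give allele-specific
TE elements. Candidate genes have a TSS within 100 kb (TSS to element
edge) of such an element and are flagged when the pseudocounted allelic
expression ratio reaches 1.5-fold either way.

## CRISPRi quantification and differential expression

The H3K27ac effect per element is log2((control + 1)/(CRISPRi + 1)) on
library-size-normalised signal; the "> 2-fold loss" count is restricted to
elements that overlapped an H3K27ac peak in the control, and means are
reported per predicted-hit stratum (0, 1, ≥ 2), with families receiving no
hits summarised separately as the untargeted control. The differential
expression test is deliberately simple and documented as such: median-of-
ratios size factors, per-gene two-sided t-tests on log2(normalised + 1)
counts, Benjamini–Hochberg correction; count matrices can be exported for a
dedicated DE tool when real data are at stake.

## Motif analysis

PWMs are read from MEME minimal format and scored as summed log-odds
against a 0-order background (uniform unless supplied). The default hit
threshold is the smallest score with background tail probability below
1e-4, computed exactly by dynamic-programming convolution of discretised
per-position score distributions for motifs up to 12 bp and by Monte-Carlo
sampling above. An element "contains" a motif when at least one hit falls
anywhere on either strand; co-occurrence fractions are computed per class
over elements longer than 60% of their family maximum (strict).

## The synthetic world

Defaults define the study conditions: a ~2-Mb genome over 4 contigs; two
LTR families of 150 copies each (ESC-active and TSC-active), consensus
length 350 bp, 12% per-base divergence (typical for murine ERVK families of
this age) with 5′ truncation of 30% of non-enhancer copies; 20% of copies
planted as TE+ enhancers (60) and 40 repeat-free TE− enhancer regions, all
with consistent lineage-specific peaks; 10% of background copies duplicated
verbatim with 1-kb flanks to create unmappable elements; 200 genes with
promoter-fragment interactions routing each planted enhancer to a target
gene (plus 5 genes deliberately linked to both enhancer types); an 8-fold
lineage expression effect for TE+-linked genes; binomial allelic counts
with a 10% planted-skew subset at p = 0.9; methylation lower at enhancers
(Beta(2,8)) than elsewhere (Beta(8,2)); and a CRISPRi signal pair with a
planted knockdown of 0.5 log2 units per predicted sgRNA hit under ~8%
multiplicative noise — a dispersion consistent with normalised,
element-averaged ChIP signal and with the recovery precision the
acceptance checks assert at their stated sample sizes. All randomness
derives from one master seed through named substreams, so identical seeds
regenerate identical worlds and layers are independent.

Because chance can hand two family copies an identical ≥ 40-bp stretch even
at 12% divergence, the generator ends with a repair pass that injects a
substitution into any element window whose sequence recurs elsewhere, so
unmappability arises from planted duplication only and planted mappability
labels are exact for every seed.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: read-level error profiles and alignment
heuristics, Hi-C contact-distance decay and interaction-calling noise, real
repeat phylogeny (consensus sequences are random, with a slot for real
Dfam/Repbase consensus FASTA), GC/antibody biases in ChIP, and
peak-caller-specific behaviour (MACS2/F-seq are replaced by the simplified
Poisson caller). Absolute counts from the original study (e.g. 634/358 TE+
enhancers) depend on external accessions and tool versions and are out of
scope; the pipeline reproduces the *logic*, verified against planted truth
and exhaustive oracles.

## Problem sizes and numerical choices

Simulation sizes were chosen so every oracle can be exhaustive: 2-Mb
genomes keep brute-force k-mer counting and Hamming scans tractable;
recoverability runs use 50-element subsets; toy panel-selection instances
stay within exhaustive C(8, 4) enumeration; normalization checks use
n = 10⁴ samples. Probability floors: PWM probabilities are floored at 1e-3
before log-odds; Poisson calling uses the exact survival function; all
ratio statistics use pseudocount 1; BH correction is used wherever multiple
tests arise. Degenerate inputs (empty reference sets, constant samples,
all-zero genes, elements shorter than the read length) raise explicit
errors or are flagged, never silently coerced.
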