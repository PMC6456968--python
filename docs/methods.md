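# Methods

This note documents the models, thresholds and design choices behind
`homoeoseq`, and what the synthetic-data tests do and do not establish
about real data.

## Setting and assumptions

The pipeline targets inbred allotetraploid (AABB) material sequenced with
short paired-end RNA-seq and analysed against a collapsed transcript
reference (one contig per gene, both homoeologs mapping to it). Under
inbreeding, a genuinely heterozygous-looking call at a position cannot be
allelic heterozygosity; it is interpreted as a mixture of the two
homoeolog copies. All downstream logic — the five-way SNP taxonomy, the
reference-haplotype concordance filter, the A/B labelling — rests on that
assumption and on the A and B copies being close (95–100% identity) but
not identical. Only substitutions are modelled end to end; alignment gaps
count toward the caller's window filter but are never emitted as variants,
and sequence editing is not indel-aware.

## Variant calling

Every read base passes a quality-window filter before entering the pileup:
an 11 bp window centred on the base (truncated at read ends) must contain
at most 6 gaps+mismatches, the central base must have phred ≥ 20 and the
window mean phred ≥ 15. A position with filtered coverage ≥ 8 is genotyped;
an alternative allele is supported when its count is ≥ 4 and either its
frequency is ≥ 10% or its count reaches 1000. The 1000-read level is
interpreted as waiving the frequency requirement (an absolute-evidence
override for very deep positions), and the 4-read level as an absolute
floor; both interpretations are recorded in the configuration so
alternatives can be swapped in. Genotypes: HOM_ALT at alternative
frequency ≥ 90%, HET when both alleles reach 10%, HOM_REF otherwise. The
90% homozygous boundary is not externally fixed; it is chosen symmetric
with the 10% heterozygote bound and exposed as `hom_frequency` — in inbred
material the homoeolog-mixture heterozygotes sit near 50%, far from either
bound, so the analysis is insensitive to it. Positions with coverage ≥ 8
and no supported alternative are kept as explicit homozygous-reference
calls: the taxonomy needs "sufficient information" cells, not just
variants. When alignments arrive as SAM, records are pre-filtered at
minimum similarity 0.8 and minimum aligned-length fraction 0.9.

The scalar `window_filter`/`call_position` functions are the reference
semantics; the production path is an exactly equivalent vectorised
implementation over read arrays, and the equivalence is asserted by
brute-force oracles in the test suite.

## SNP taxonomy

The genotype matrix keeps positions with a supported non-reference call in
≥ 1 variety and ≥ `min_informative_varieties` cells at coverage ≥ 8
(default 5; frequency-distribution reports conventionally use 7 — both
are plumbed through one parameter, and the active value is echoed in the
config). Classification is a total decision table over the non-MISSING
cells; a *carrier* counts HET and HOM_ALT alike. Frequency bins are
half-open intervals of width 0.13 starting at 0.05 — a scheme inferred
from the published example bin [0.18, 0.31) containing 3/12 = 25% with
seven bins; the origin and width are parameters because only that one
bin's bounds are fixed externally. Frequencies of exactly 1.0 are placed
in the top bin. A SNP is *rare* with ≤ 1 carrier; array candidates are
SIMPLE or HEMI rows with ≥ 3 carriers. The partition summary reports the
multi-genotype class and the non-rare hemi-SNP count as two separate
statistics; the package does not conflate them.

## Phasing and homoeolog sequences

Fragments are read pairs reduced to alleles over the heterozygous sites
they cover; a base matching neither allele, or mates conflicting at a
shared site, becomes a gap (conservative evidence handling), and
fragments informative for < 2 sites are dropped. Connected components of
the site-covisibility graph are candidate blocks. MEC is minimised
exhaustively over the 2^(n−1) bipartitions for blocks of up to
`exhaustive_site_limit` = 15 sites (fragments deduplicated to patterns,
the search vectorised over bitmasks); larger blocks use a spanning-tree
majority-linkage seed plus hill climbing over single-site and suffix
flips with a small set of deterministic restarts. On planted instances
with ≤ 10 sites the heuristic attains the exhaustive optimum in every
seeded test.

Blocks are retained at MEC ≤ 10 with one haplotype carrying ≥ 90%
reference alleles; that haplotype is labelled A (its complement B) when
its match is ≥ 90%. The two 90% rules are treated as one coherent
criterion with separate knobs (`min_reference_concordance`,
`min_subgenome_match`), since the text defining them does not distinguish
one threshold applied twice from two thresholds. An exactly 50/50 tie
leaves the block unlabelled and excluded from expression analysis rather
than fabricating an assignment.

Editing substitutes the A allele into the A sequence and the complement
into B at each phased site; homozygous-alternative (fixed) variants are
substituted into both. Multi-block transcripts are split into per-block
records whose regions abut at the midpoints between neighbouring blocks
and tile the transcript — the unphased gap between blocks carries no
discriminating site, so the midpoint is as good as any cut and keeps the
records non-overlapping and exhaustive.

In the end-to-end pipeline the heterozygous sites offered to the phaser
are restricted to positions the multi-variety taxonomy classifies as
inter-homoeolog. This is a deliberate design choice: a varietal hemi-SNP
of the focal variety would phase cleanly onto one haplotype but would
misdirect reads of non-carrier varieties during double-reference
assignment. Constitutive sites are exactly the sites shared by the whole
panel. A consequence worth knowing: with the reference built from the A
subgenome, the all-reference pattern is the A haplotype, so retained
blocks on clean data have concordance 1.0 and the concordance filter only
bites on noisy or contaminated blocks.

## Read assignment and expression

A pair is scored against the A and B variants of each block it overlaps
(score = matches − mismatches over the block region, a deterministic
stand-in for mapper alignment scores; for substitution-only variants this
reduces to allele votes at the phased sites). The pair counts once, for
the variant with the strictly higher score; ties — including every pair
covering no phased site — are ambiguous and dropped. Only within-block
A/B ambiguity is modelled; multi-gene mapping ambiguity is out of scope
and noted in the configuration.

Counts are merged into five pseudo-replicates (Altar84+Capeiti8+Claudio;
Creso+Edmore+Kofa; Meridiano+Neodur+Saragolla; Strongfield+Svevo;
Valnova+Yavaros79 by default — the grouping is a parameter). Size factors
are median-of-ratios; with no all-positive row the geometric means fall
back to positive subsets with a warning. Dispersions are pooled
method-of-moments estimates across tissue conditions, with a trend
α(µ) = a₀ + a₁/µ fitted by non-negative least squares and the per-unit
value taken as max(empirical, trend) — conservative for testing. The GLM
Wald test fits a log-link NB regression with tissue and subgenome factors
(offset log s_j) per gene block and BH-adjusts over blocks (α = 0.001).
The per-tissue test is a conditioned NB exact test of the A vs B summed
counts with pooled dispersion, Bonferroni-corrected within each tissue
(α = 0.01); the exact conditional sum is evaluated with vectorised log
pmfs and switches to a normal approximation only above 10⁶ total counts.
Reported log₂ fold-changes come from normalised means with a 0.5
pseudocount on both haplotype means (no external zero-handling rule
exists, and the pseudocount keeps ratios finite); units with |log₂FC| > 7
after this are excluded as artefacts. Genes with ≥ 2 tested blocks are
concordant when no two blocks have strictly opposite fold-change signs.

## Assembly QC

A hit (pre-filtered at ≥ 80% identity) is accepted when ≥ 60% of its
contig, > 80% of its gene, or ≥ 200 bp. Span fraction is the union of
accepted hit intervals over the gene length; the minimal contig count
achieving that union is computed exactly (subsets in increasing size) up
to 12 contigs and by greedy largest-gain cover beyond. For homoeolog copy
estimation, "identity close to 100%" is fixed at ≥ 99.0%
(`a_identity_floor`; only the B rule — within 1% of the paired identity —
is externally quantified, and a symmetric 1% band near 100 is the natural
reading); hits between the bands are putative paralogs. Overlap removal
keeps the higher-identity hit and trims the other. The five copy
categories use a 0.8 full-copy coverage threshold and a 0.2 presence
floor — the published category semantics come without printed boundaries,
so both are parameters in `QCParams`.

## The synthetic generator

The generator emulates the *structure* of an elite inbred tetraploid
panel, not its noise:

* Homoeolog pairs diverge by i.i.d. substitutions at
  `homoeolog_divergence` (default 0.02, i.e. ~98% identity, inside the
  95–100% band); divergent sites are the inter-homoeolog class.
* A fraction of genes (`single_copy_fraction`, default 0.2) lack the B
  homoeolog in all varieties — the substitution-only realisation of a
  homoeolog-segment deletion — and host the simple (diploid-behaviour)
  SNPs. Hemi sites are subgenome-specific substitutions in a carrier
  subset; multi-genotype sites add carriers homozygous for the
  alternative; misassembly sites give the reference a base no variety
  carries. Carrier counts follow P(k) ∝ 1/k by default (rare variants
  most frequent, as in elite panels); the varietal allele-frequency
  spectrum is not externally fixed, so the distribution is a parameter.
* Reads are 2 × 100 bp pairs, fragment 550 ± 40 bp, with per-base errors
  at `base_error_rate` (default 10⁻³) flagged at phred 10 against a
  phred-30 background, so the caller's quality filters are exercised
  deterministically. Pair placement is clipped into the transcript so
  per-base coverage is approximately uniform at `depth` per homoeolog;
  the terminal coverage ramps of real libraries are deliberately not
  modelled — with the published coverage-8/count-4 filters, ramp cells at
  coverage 8–20 flip true heterozygotes to homozygous-reference at rates
  of 10⁻¹–10⁻², which is a property of marginal coverage, not of the
  classification logic the round-trip tests probe.
* Counts are NB with dispersion 0.05 (pseudo-replicates of inbred lines
  are tight), lognormal baselines around `expr_mean`, per-tissue
  lognormal factors, and a constitutive per-gene bias of ±`bias_log2fc`
  in a `bias_fraction` of genes, split evenly between A-up and B-up.
  Column depth multipliers are drawn from U(0.75, 1.25) so size-factor
  recovery is testable.

Not emulated: realistic error profiles, indels, splice isoforms, GC and
positional bias, mapping ambiguity between genes, end-ramp coverage,
variety-specific expression differences. Passing recovery tests therefore
demonstrate the correctness of the algorithms under their stated
assumptions, not robustness to real-library artefacts.

## Problem sizes and numerical choices

The end-to-end recovery suite runs 200 genes × 13 varieties × 3 tissues at
10× per homoeolog per tissue (30× merged per variety) with zero error and
no expression bias — the regime in which the chain is provably lossless:
classification, phasing labels and read assignment are asserted exact.
Expression bias is a separate axis: the statistics suite uses 2000
simulated null units (false-positive control at BH-adjusted α = 0.001),
800 biased units at |log₂FC| = 2 (power, assessed on units with baseline
mean ≥ 200), and bias recovery as the mean estimated log₂FC over units
with baseline mean ≥ 500 (a single unit's estimator has sampling sd ≈ 0.12
at these depths, so the aggregate is the meaningful ±0.2 check). The
classifier is verified against an independent rule-table oracle over every
genotype multiset of up to 13 varieties; MEC optimisation against
exhaustive bipartition search on 500 random ≤ 10-site instances.

Ties and degenerate inputs: allele argmax ties resolve to the
alphabetically first base; equal-score read pairs are dropped, not
assigned; blocks with < 2 sites are not blocks; all-zero count units are
excluded from testing; a transcript with no retained block but with fixed
variants still yields an edited (A = B) record. Dispersions are floored at
10⁻⁸; GLM non-convergence excludes the unit with a warning rather than
reporting a doubtful p-value.

## Known limitations

Indels are neither called nor phased. The phasing heuristic beyond 15
sites is a local search with deterministic restarts — optimal on every
tested instance but without a worst-case guarantee (full max-cut-style
machinery is out of scope). The per-tissue exact test assumes the pooled
dispersion applies to both haplotypes of a unit. CLI stages serialise
per-position call tables as plain TSV, which is comfortable at
demonstration scale but not designed for full-transcriptome volumes; the
in-memory pipeline functions are the scalable surface.
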