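# Methods

## Scope and data model

`methylhet` quantifies DNA methylation heterogeneity from bisulfite reads at
two levels: within a sample (read-level epiallele statistics) and between
samples (dispersion of tile-level methylation). Everything is anchored to a
CpG coordinate frame: the ordered 0-based positions of the C of every
forward-strand CG dinucleotide per contig. A read is reduced to an
*epiread* — its ordered methylation calls (M/U/missing) over a run of
consecutive reference CpGs — and all downstream statistics consume epireads.
Coordinates are 0-based half-open throughout; evidence from both strands of
a symmetric CpG collapses onto the forward-strand C, the standard WGBS
treatment.

Extraction from SAM/BAM decodes, at each reference CpG overlapped by the
aligned portion, C→M / T→U on top-strand alignments and G→M / A→U at the G
of the CpG on bottom-strand alignments (Bismark `XG` and BSMAP `ZS` tags are
honored; otherwise the mapping strand decides). Anything else — mismatch,
deletion, clipped base — is a missing call. Base qualities are ignored by
design: extraction is minimal and deterministic, and SNP-aware filtering is
out of scope. Overlapping mates are deduplicated first-mate-wins, the
simplest rule that never double-counts a CpG observation.

## Heterogeneity metrics

Loci are windows of 4 consecutive CpGs, non-overlapping by default (step 4);
a sliding mode (step 1) exists but correlates neighbouring loci and is not
the default. For a locus with epiallele frequencies *p₁…p₁₆*:

- epipolymorphism `1 − Σ pᵢ²` (range 0 … 0.9375),
- entropy `−Σ pᵢ log₂ pᵢ` in bits (0 … 4), also emitted as `H/4` because
  published entropy values are frequently on a normalized scale and the
  convention is rarely stated; tables carry both columns,
- locus discordance: the fraction of the locus's reads carrying both an M
  and a U.

Only reads covering all four CpGs with called states enter the pattern
table, and a locus needs at least 10 such reads (configurable; the
historical methclone default of 60 is reachable via `min_reads`).

PDR is computed per CpG rather than per locus, following the
discordant-read literature: a read is *eligible* if it has ≥ 4 called CpGs,
*discordant* if its called states mix M and U; each CpG's PDR is the
discordant fraction of eligible reads covering it, defined only when more
than ten eligible reads cover it (i.e. ≥ 11 — every "more than ten" filter
in this package is strict). The sample score is the unweighted mean over
defined CpGs; a pooled-read variant is available through the per-locus
discordance column. Undefined values are NaN everywhere and are never
silently zero, because a zero is a legitimate (fully concordant) value.

## Methylome summaries

Per-CpG beta = methylated calls / total calls, undefined without coverage.
Tiles partition each contig into fixed 5-kb half-open windows; a tile's
methylation is the unweighted mean of its defined CpG betas, and the tile is
eligible only when it contains a CpG and its mean per-CpG read depth
strictly exceeds 10. The "covered by more than ten reads" rule is
interpreted as mean depth across the tile's CpGs; a stricter every-CpG mode
is available by flag since the averaging convention is genuinely ambiguous.
The per-sample CV is sd/mean (sample sd, n−1) over eligible tiles and needs
at least two of them. Global methylation is the unweighted mean beta over
covered CpGs, with a coverage-weighted (pooled-call) mode available.

The metagene profile maps CpG betas into 20 fixed-bp flank bins on each
side (2 kb flanks) and 100 length-scaled gene-body bins, flips minus-strand
genes, takes each gene's per-bin mean and then the unweighted mean across
genes; genes shorter than the body-bin count in bp are skipped and counted.
Defaults are a deliberate choice — fine enough to show the TSS dip and
gene-body elevation, coarse enough for small inputs.

Region-wise group comparison on user-supplied regions uses the
Mann–Whitney U test — exact when both groups have ≤ 8 samples and no ties,
tie-corrected normal approximation otherwise — with Benjamini–Hochberg
adjustment across regions. This is a generic region comparison, not a DMR
segmentation method; segment discovery is consumed, not performed.

## Clinical association

Samples are dichotomized at the cohort median of any per-sample metric,
ties to the low stratum (configurable): the cut rule for "high" vs "low"
heterogeneity is rarely reported in the literature, so the package defaults
to the least parameterized one and records it. Kaplan–Meier and the
two-sample log-rank test are implemented directly from their definitions
(product-limit; observed − expected over hypergeometric variance, 1 df),
with censored-at-event-time records kept at risk at that time; the
test-suite cross-checks both against an independent survival library on
random data. Loci are assigned to CNA segments by midpoint overlap in
half-open intervals (full containment by flag), and the inside/outside
contrast is paired across samples with a Wilcoxon signed-rank test.

## The synthetic generator

The generator emulates the epiallele structure of paired high/low-risk WGBS
cohorts; it is the package's source of ground truth, not a sequencing
simulator. Per locus, the pattern distribution is a clonal mixture:

- a **founder** clone, fully methylated with probability
  `founder_meth_prob` (default 0.7, matching the mostly methylated
  background of a tumor genome with global methylation in the 60–75%
  range), else fully unmethylated;
- `clonality − 1` **derived** clones: distinct partially-methylated
  (discordant) epialleles, drawn without replacement with probability
  proportional to `d^h (1−d)^(4−h)` where `h` is the number of CpGs mutated
  away from the founder and `d = clone_divergence` (default 0.5 = all 14
  discordant patterns equally likely);
- mixing weights from a symmetric Dirichlet(`clone_mix_alpha`, default 1.0),
  sorted so the founder receives the largest weight.

The dominant-founder constraint and discordant-only derived clones are
deliberate: they make entropy, epipolymorphism and expected PDR jointly
monotone in the derived-clone mass, so the three metrics rank loci
concordantly across a clonality gradient — the qualitative behaviour
observed in real tumors. Without them, PDR (which is linear in the pattern
distribution) is provably insensitive to reweighting clone proportions, and
the metrics decouple.

Reads are whole-locus observations: coverage per locus is negative binomial
(mean 25, matching a realistic WGBS median depth; dispersion 5, Poisson in
the large-dispersion limit), each read draws a pattern and then flips every
CpG state independently with `error_rate` (default 0.01), which models
bisulfite conversion error plus residual local disorder. A
`partial_fraction` mode truncates a uniform prefix/suffix of states to
exercise missing-data handling. Because the flip channel is a known 16×16
transition matrix, `expected_metrics` gives every locus's exact
error-perturbed entropy, epipolymorphism and discordant mass — the analytic
oracle for all plug-in estimates, including the exact multinomial plug-in
bias `E[1 − Σ p̂²] = (1 − 1/n)(1 − Σ p²)` at coverage n.

Cohorts: two groups of `n_per_group` samples (default 20 per arm, a
realistic discovery-cohort size). The high-heterogeneity arm receives
`group_effect` as an additive shift, by default +0.05 on the per-CpG
disorder rate — the one knob that moves PDR, entropy and epipolymorphism
together (shifting only the clone-mixing concentration is also supported,
but cannot move PDR, for the linearity reason above). Survival is
exponential with hazard `λ₀ · exp(β · h̄)` where `h̄` is the sample's mean
expected epipolymorphism (defaults λ₀ = 0.05 per time unit, β = 2,
independent exponential censoring at rate 0.02) — the simplest model with a
controllable heterogeneity→hazard link for log-rank power studies. Each
sample draws from a child generator seeded deterministically by
(master seed, sample index), so cohorts reproduce read-for-read.

What the generator does **not** model: sequencing quality and PCR
duplicates, mappability, real genome sequence composition (the synthetic
contig's filler alphabet contains no G, so CpGs exist only where placed),
correlated epimutation along the genome, tumor purity, and SNPs. Passing
tests therefore demonstrate the correctness of the statistics and the
plumbing under a known generative model, not robustness to real-data
artifacts upstream of epiread extraction.

## Numerical and design notes

- Determinism: all randomness flows from `numpy` Generators seeded
  explicitly; pipeline runs write a manifest of SHA-256 checksums and
  identical config + seed reproduces identical files.
- Entropy uses only nonzero frequencies (0·log 0 = 0); metrics on empty
  tables are NaN and flagged, never 0.
- The problem sizes in the test-suite and acceptance script (e.g. 2,000
  loci for the bias law, 60 loci per clonality level, 1,000 loci × 30
  samples end-to-end) were chosen to keep Monte-Carlo error comfortably
  below the asserted tolerances while remaining quick on a laptop.
- Known limitations: no CHG/CHH contexts; no between-sample epiallele-shift
  statistic; Cox regression is deliberately not wrapped (the survival
  machinery here covers stratified KM + log-rank); exact Mann–Whitney
  p-values fall back to the tie-corrected normal approximation when ties
  occur in small samples.
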