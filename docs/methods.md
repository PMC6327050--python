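# Methods

This note documents the statistical procedures implemented in `regfine`,
the assumptions behind the synthetic-data generators, and the numerical
conventions used where a choice was genuinely open.

## Association and fine-mapping (`regfine.assoc`)

**Base test.** The per-variant test is the classical 2×2 allele-count
cross-product odds ratio: with risk/non-risk allele counts a, b in cases
and c, d in controls, OR = ad/bc, SE(log OR) = √(1/a + 1/b + 1/c + 1/d)
(Woolf), and a two-sided normal p on the log scale. Any zero cell triggers
the Haldane–Anscombe correction (+0.5 on all four cells). This
closed-form test was chosen over genotypic logistic regression because it
matches the additive per-allele OR that GWAS meta-analyses report and is
fully oracle-checkable; logistic regression appears only in the
conditional analysis. Monomorphic variants are flagged, not raised.

**Meta-analysis.** Inverse-variance fixed effect: weights wᵢ = 1/seᵢ²,
pooled β = Σwᵢβᵢ/Σwᵢ, pooled se = (Σwᵢ)^(-1/2). Heterogeneity by
Cochran's Q = Σwᵢ(βᵢ − β̂)² on χ²(k−1); for k = 1 the homogeneity p is 1
by the df-0 convention.

**INFO score.** For posterior triples (p₀, p₁, p₂) per sample, with
eᵢ = pᵢ₁ + 2pᵢ₂ and fᵢ = pᵢ₁ + 4pᵢ₂,

    info = 1 − Σ(fᵢ − eᵢ²) / (2N·θ̂(1−θ̂)),  θ̂ = Σeᵢ/(2N).

Monomorphic variants (θ̂ ∈ {0,1}) return 1 by convention, and the ratio is
clipped to [0,1] because sampling noise can push it marginally outside.
The default retention threshold is 0.8.

**LD.** r² is the squared Pearson correlation of dosage vectors
(composite LD) — phase is not required by any input format, and dosage r²
is the standard surrogate. Block capture retains variants with
MAF > 0.01 and r² ≥ 0.4 with the lead; variants whose r² is undefined
(constant dosage) count against the capture fraction.

**Conditional analysis.** Logistic likelihood-ratio test of
{intercept, covariate, test} vs {intercept, covariate}, with χ²(1) p.
A test dosage with |r| > 0.999 to the covariate is flagged collinear; an
all-constant covariate is dropped, reducing to the unconditional LRT;
non-convergence is flagged rather than raised.

## Disomy-restricted eQTL (`regfine.eqtl`)

Blasts are filtered to copy number exactly 2 for the focal chromosome
before testing (samples without a call are excluded by default). The test
is the tie-corrected Kruskal–Wallis statistic with average-rank ties,
H referred to χ²(groups−1); all-identical data returns H = 0, p = 1
because the tie correction degenerates. The effect size is the ratio of
mean expression in risk homozygotes to non-risk homozygotes (arithmetic
mean by default, geometric optional). Whether the published fold of this
design is homozygote-vs-homozygote or per-allele is not derivable from a
single reported number; the homozygote ratio is the package's documented
default interpretation.

## Allele-specific ChIP (`regfine.allelic`)

Reference-mapping bias arises because reads carrying the non-reference
allele align with one extra mismatch; it is corrected by N-masking common
SNP positions in the reference prior to alignment. `mask_reference`
performs the edit (1-based positions, length preserved); the simulator
models the bias as read loss — an alternate-allele read fails to map with
probability 1 − 1/ref_bias unless the site is masked — so the unmasked
observed alt fraction has closed-form expectation
q = f / (f + (1−f)·ref_bias).

Counting excludes reads below MAPQ 30 (mirroring the upstream alignment
filter); bases below quality 20, or matching neither allele, accumulate in
`k_other`. The imbalance test is the exact binomial against p₀ = 0.5,
two-sided by the minimum-likelihood method (sum of the probabilities of
all outcomes no more likely than the observed one); the central
(2·min-tail, capped at 1) and one-sided variants are options since the
choice is rarely stated in publications. For calibration diagnostics on
discrete counts the test exposes mid-p (ties weighted ½) and the
randomised/fuzzy exact p (ties weighted by a supplied U(0,1) draw), the
latter being exactly uniform under the null; the plain minlike p remains
the reporting default. A site is labelled allele-specific only when the
assay is imbalanced at α while its input-DNA control is not, both at the
same α (default 0.05) — the simplest faithful reading of an
input-gated call.

## ChIP-qPCR (`regfine.qpcr`)

Standard curves are least-squares fits of Cq on log₁₀(quantity);
efficiency = 10^(−1/slope) (slope −1/log₁₀2 ≈ −3.32 for perfect doubling).
Non-negative slopes flag the curve invalid. Percent input is
100·ip/(input/input_fraction), with the input fraction defaulting to 1%;
fold enrichment is the ratio of percent inputs (target over IgG). Both are
invariant to a common multiplicative rescaling of all quantities.
Allele-specific primer preference is the ratio of curve-interpolated
quantities for matched vs mismatched template; an undetected mismatched
template (Cq at the instrument ceiling) yields a censored lower bound.
Replicate comparisons use Welch's t-test (unpaired default, paired
option); two zero-variance equal groups return p = 1 by convention.

## Regulome annotation (`regfine.annotate`)

Peaks are BED-convention 0-based half-open intervals; TSSs are 1-based
points. The TSS–peak distance is 0 inside the peak and otherwise the gap
to the nearest peak edge; the assignment window (default 1000 bp) is
inclusive, and TSS strand is ignored — "within 1 kb" has no published
edge or strand convention, so both choices are documented here. Hi-C
contacts are symmetric bin-pair triples; bins are floor(position/
resolution) on 0-based coordinates, intervals are linked when any bin pair
reaches the threshold, interval pairs sharing a bin are linked by
convention, and queries beyond the matrix extent are flagged no-data. No
default contact threshold is shipped: the value is study-specific and must
be supplied. Motif scanning is IUPAC-aware Hamming matching on both
strands; minus-strand hits are reported at their forward leftmost
coordinate and palindromic double hits collapse to strand "both". A
masking 'N' in the sequence matches only an all-base consensus code.

## Expression programs (`regfine.programs`)

Spearman correlation uses average-rank ties and the t approximation
t = ρ√((n−2)/(1−ρ²)) for two-sided p; |ρ| = 1 is flagged exact-monotone
with p = 0, and constant genes are NaN. The correlated set takes genes
with p strictly below 5×10⁻⁴ (driver excluded); Benjamini–Hochberg
adjustment is available but off by default, since the published threshold
is conventionally applied to unadjusted p.

Overlap enrichment treats the smaller list B as |B| draws with success
probability |A|/N and reports the upper tail P(X ≥ x) of
Binomial(|B|, |A|/N) — the binomial (with-replacement) null named in this
literature — with the hypergeometric draw-without-replacement null as an
option. The universe must be stated explicitly (genes present in both
input tables, recorded in the output); sets that stray outside it are an
error naming the offenders. Top-k DE lists are ranked by ascending
adjusted p, ties broken by descending |log fold change|, then gene id.

Translocation outliers are scored as z = (TPM − mean)/SD with cohort mean
and sample SD (ddof = 1) computed over non-translocated cases only; the
sample SD is the conservative choice for small cohorts. A zero-SD cohort
is flagged.

## Breakpoints and RSS scanning (`regfine.breakpoints`)

Flanks are extracted around a 1-based breakpoint position: downstream
starts at position+1, upstream ends at position−1, so
upstream + breakpoint base + downstream reconstructs the window exactly;
flanks running off the contig are truncated and flagged. The RSS scanner
finds every heptamer placement on both strands (default consensus
CACAGTG, 0 mismatches — heptamer conservation is functionally strict),
then searches for the nonamer (ACAAAAACC, default ≤1 mismatch) at offsets
matching the 12 or 23 bp spacer classes ±1 on the same strand; hits with a
nonamer are full-RSS, otherwise heptamer-only. These element sequences
are canonical V(D)J values supplied as configurable defaults. (The
literature this design follows speaks of a RAG "hexamer"; the canonical
RAG elements are a heptamer and nonamer, and the canonical heptamer is
used here.) Breakpoints are categorised by the best hit within a proximity
window: full-RSS-proximal ≻ heptamer-only-proximal ≻ no-RSS. Under a
uniform base model the expected heptamer false-positive count in a
length-L sequence is 2(L−6)·4⁻⁷, the closed form the background
calibration test checks.

## Synthetic data (`regfine.simulate`)

Every generator is a pure function of a `SimulationConfig` (one seeded
stream per dataset), so equal configs give byte-identical outputs.
Defaults encode the study dimensions the pipeline is modelled on: 824
cases / 5200 controls, risk-allele OR 1.45 at MAF 0.3 (the MAF itself is
a chosen value, not a reported one); an expression cohort of 60 blasts
with 44 disomic and a 1.8-fold risk-homozygote effect; ChIP pileups at
depth 100; a 117-sample cohort with 150 latent-factor target genes and a
150-gene DE label list; two translocated cases at Z = 4.6; 313 peaks with
83/313 of TSSs within 1 kb; and canonical RSS elements in breakpoint
flanks.

Modelling assumptions worth knowing:

- Case genotypes are Hardy–Weinberg at the frequency implied by the
  allele-scale odds ratio (odds_case = OR·odds_control), so the planted OR
  is exact at the allele level.
- Expression is log-normal on the TPM scale (log-additive dosage effect,
  Gaussian log-noise with sd 0.5 by default; baseline 50 TPM). This is an
  assumption about a reasonable positive-support noise model, not an
  inference about any real cohort; real blast expression is
  overdispersed, multi-modal across subtypes, and correlated between
  genes in ways the single-factor model does not capture. A green
  recovery test therefore establishes estimator correctness under the
  stated model, not robustness to real-data structure.
- Reference bias is multiplicative read retention (alt reads lost with
  probability 1 − 1/bias when unmasked), matching the mechanism N-masking
  corrects; it does not model soft-clipping or indel-driven bias.
- The driver gene's log-expression *is* the latent factor, so planted
  targets correlate with it at exactly the configured magnitude.
- Translocated cases get the driver planted deterministically at
  mean + Z·SD; their other genes are drawn from per-gene log-normal fits
  to the cohort.
- Peaks are laid on a jittered grid with ≥4-window gaps so that
  "within-window" truth is unambiguous; non-proximal TSSs are placed
  strictly beyond the window but within 2 windows of a peak.

## Numerical conventions

- Coordinates: 1-based for point sites (VCF/TSS convention), 0-based
  half-open for intervals (BED convention); conversions happen at module
  boundaries.
- Degenerate inputs are flagged on result objects (`undefined`,
  `collinear`, `censored`, `uncovered`, `no_data`) rather than raised,
  except where the input violates a format contract, which raises with
  the offending value named.
- Exact binomial ties are resolved at relative tolerance 1e-10 on the
  pmf when classifying "as likely as observed" outcomes.
- The pipeline summary JSON is sorted-key, timestamp-free output, so
  fixed-seed runs are byte-identical; timing and version information go
  to the run log instead.

## Known limitations

- The allelic model has no overdispersion (no beta-binomial option); a
  single biological replicate per site is assumed.
- The Kruskal–Wallis p uses the χ² approximation; at very small group
  sizes the permutation null deviates by up to a few hundredths, as the
  test suite quantifies.
- Hi-C linking is thresholding of normalised contacts, not a loop-calling
  statistic; the threshold is intentionally a required user parameter.
- The conditional analysis assumes an additive dosage coding and does not
  adjust for population structure.
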