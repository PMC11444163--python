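# Methods

This note documents the models behind each `pairscan` stage, the defaults
and why they were chosen, what the synthetic cohort generator does and does
not emulate, and the package's numerical conventions and limitations.

## Coordinates, bins, and formats

All internal coordinates are 0-based half-open; the only conversion happens
at the VCF boundary (POS is 1-based, so internal `start = POS - 1`).
Chromosome names are "chr"-prefixed. Bin grids tile each chromosome with
consecutive fixed-width bins (default 1 kb); the final partial bin of a
chromosome is retained rather than dropped, and its true width is used
wherever a bin width matters (coverage fractions, conservation checks).
Segmented copy-number inputs follow the convention of segment-caller
output; whether an upstream caller's segments are 1-based inclusive cannot
be inferred from the files themselves, so anyone comparing against another
pipeline's projections should check that convention first.

## Binned paired copy-number scan

Per sample, the copy number of bin *b* is the length-weighted average of
intersecting segments, `cn_b = Σ_i cn_i·ov_i / Σ_i ov_i`. Bins whose
covered fraction falls below `min_covered_fraction` (default 0.5, a
balance between tolerating small inter-segment gaps and not inventing copy
numbers for mostly-uncovered bins) are masked. The projection conserves
length-weighted copy mass exactly over covered territory, which the tests
assert to 1e-9.

Per bin, gains (post > pre) and losses (post < pre) are tested across
patient pairs with one-sided Wilcoxon signed-rank tests. Conventions:

- zero differences are dropped (the classical convention for this test);
  a bin whose informative pairs all tie yields p = 1 with a degenerate
  flag, not an error;
- tied absolute differences get mid-ranks, with the usual tie correction
  in the normal-approximation variance;
- the **exact** null (equivalent to enumerating all 2^n sign assignments,
  computed by rank-polynomial convolution) is used when the effective n is
  ≤ 25 and tie-free; otherwise a continuity-corrected normal
  approximation. The acceptance suite checks the exact branch against a
  literal 2^n enumeration for all n ≤ 10;
- bins with fewer than `min_pairs` (default 10) informative pairs are
  reported untested rather than contributing unstable tiny-n p-values;
- both one-sided p-values are emitted per bin along with nominal and
  Benjamini–Hochberg-adjusted values, since a gain panel and a loss panel
  ask two one-sided questions; users who prefer a single two-sided test can
  Bonferroni-combine the two columns.

`locus_summary` applies the same machinery to a single region
(length-weighted mean copy per sample, then the paired test), with a
Spearman helper for copy-vs-expression comparisons.

## Emergent-mutation rules

A coding mutation *qualifies* iff it is called in the post sample, has no
call with the same (chrom, pos, ref, alt) in the paired pre sample, and is
protein-altering (`missense, stop_gained, stop_lost, start_lost,
frameshift, inframe_indel, splice_donor, splice_acceptor` by default).
Presence/absence is decided purely on call-set identity — no re-genotyping
from reads — because annotated call sets are the input contract. Callers
disagree about callability, so an optional per-sample callable-regions mask
can veto "newly arising" claims at sites that were not assessable
pre-treatment; it is off by default. Emergent noncoding variants must
additionally be absent from every treatment-naive sample (a filter that
removes large numbers of noncoding calls of unknown significance), and only
those recurrent in ≥ 2 pairs are reported. Recurrence tables count at the
sample level and report patient multiplicity separately. The ΔVAF-vs-Δpurity
diagnostic quantifies why VAF comparisons of shared mutations mostly track
purity changes, motivating the restriction to newly arising calls.

## Amplification and tandem-duplication classification

A sample is *amplified* iff the length-weighted mean copy of the gene OR of
its enhancer is ≥ 4 — the threshold is inclusive, which the tests probe at
exactly 4.0. "A TD involving the region" means a duplication-type SV whose
span overlaps the region by ≥ 1 bp; a stricter containment mode (span must
cover the whole region) is available by flag since either reading is
defensible. Complex/chained SV clusters are out of scope; each DUP record
counts independently. The TD-free vs TD-backed copy comparison uses the
two-sided rank-sum test (high TD-free copy levels are the signature
expected when extrachromosomal DNA, which reaches much higher amplitude,
drives the amplification).

## Negative-binomial differential expression

The engine is an in-repo NB log-link GLM, not a wrapper: exact parity with
any external tool is a non-goal; the contract is distributional (calibrated
type-I error under the null, power against planted fold changes), which the
acceptance suite measures.

- **Normalization**: median-of-ratios size factors against the per-gene
  geometric mean, rescaled to geometric mean 1; if no gene is positive in
  all samples the ratios fall back to each sample's positive genes (with a
  warning).
- **Design**: intercept, patient indicators (paired mode), timepoint
  (post = 1), then covariates (purity, batch dummies). Collinear columns
  are dropped greedily with the intercept and timepoint protected, and the
  dropped names are reported (`result.attrs`); batch aliased with patient
  labels is the common case.
- **Dispersion**: per gene, a Pearson moment estimate after a Poisson fit
  (solving Σ(y−μ)²/(μ+αμ²) = residual df by bisection), floored at 1e-8,
  then shrunk geometrically (50/50 in log space) toward a fitted
  mean-dispersion trend α(m) = a₀ + a₁/m. The shrinkage stabilizes
  small-cohort estimates without the machinery of full empirical-Bayes
  engines.
- **Fitting**: IRLS with a 1e-8 ridge on the normal equations. The ridge
  matters only when a covariate cell is all-zero (e.g. a patient with no
  counts for a gene), where unpenalized coefficients drift to −∞; its bias
  is orders of magnitude below reporting precision. Convergence is declared
  at a max coefficient step < 1e-6 (80 iterations cap); non-converged genes
  are flagged with NaN statistics.
- **Inference**: Wald statistic on the timepoint coefficient referred to a
  t distribution with the residual degrees of freedom — with ~30 patient
  indicators in a 60-sample design, the normal reference is visibly
  anticonservative while the t reference passes KS uniformity under the
  null. BH FDR across genes; all-zero genes are excluded and flagged.

The variance-change test is a plain two-sided F test on log2(x+1) values —
appropriate for the "did expression become more variable after treatment"
question on approximately log-normal expression. `batch_center` is a
deliberately simple location-only batch adjustment (per-gene per-batch
median subtracted, global median restored; exactly idempotent), documented
as a stand-in where a full count-level batch correction is unavailable; a
flag skips it. `plot_transform` (log2(count/sf + 1)) is likewise a simple
monotone variance-flattening substitute for heavier stabilizing transforms,
used for plotting and scoring only — never for testing.

## Scores

- **ssGSEA**: genes ranked by decreasing expression (mid-ranks on ties);
  the in-set ECDF is weighted by rank^τ (τ = 0.25, the common convention
  for this statistic), the out-set ECDF is unweighted; the score is the sum
  of (ECDF_in − ECDF_out) over all positions. Being rank-based it is
  invariant under strictly increasing transforms, which is asserted.
  Optional normalization divides all scores by (max − min) over the
  score matrix. A set with an empty out-set or empty intersection is an
  error by design.
- **AR/NE phenotype scores**: the published integrated-score construction
  is cited in the literature rather than specified, so the package uses a
  transparent approximation with the same bounded scale: the cosine
  similarity between a sample's z-scored expression over the signature
  genes and the signature's +1/−1 direction template. Scores live in
  [−1, 1], so the conventional NE-high threshold (> 0.4) is meaningful.
  Cosine (rather than centered Pearson) keeps the score defined for
  one-directional templates. This is an approximation and is labeled as
  such.
- **Subtype scores**: mean z-scored expression of each subtype's key
  transcription factors (supplied as GMT config, not hard-coded). Pair-level
  score changes feed a PCA (columns centered and unit-scaled, constant
  columns dropped with a note); a pair is an outlier when its squared
  Mahalanobis distance in the leading-2-PC space exceeds the chi-square
  0.95 quantile (df = components kept) — a standard outlier rule with the
  quantile configurable.
- **Isoform fractions**: per sample, transcript abundance over the summed
  abundance of the gene's transcripts; samples with zero totals are
  undefined (NaN + flag), never 0/0.

## Burden screen, interaction models, survival

The genome-wide screen regresses the target gene's (log) expression on each
gene's functional protein-coding mutation burden plus tumor purity by OLS;
genes with no mutated sample are not evaluable. Two-sided t tests on the
burden coefficient, BH q, and QQ coordinates are emitted; the screen
reports nominal p with the QQ plot carrying the multiplicity story.
"Functional protein-coding" reuses the emergent-mutation impact vocabulary.
The exposure × mutation interaction model is ordinary least squares
(statsmodels); degenerate designs (single-level exposure, empty
exposed-mutated cell) fall back to estimable submodels with notes.

Median splits assign "high" to samples strictly above the median; values at
the median go low (a documented tie rule — the choice matters for odd
cohorts). Survival machinery is implemented in-repo: Kaplan–Meier with
Greenwood standard errors, two-group log-rank, and Cox regression
maximizing the Efron-tie partial likelihood by Newton–Raphson with step
halving to gradient norm < 1e-8. Monotone likelihoods (complete
separation) are detected by coefficients escaping ±15, capped, and
flagged. The treatment-benefit question uses a Cox product term
(expression-group × treatment); a stratified per-treatment log-rank view
accompanies it, since the product-term and stratified formulations answer
slightly different questions.

## Candidate-element nomination

Within a window around the gene, a bin must simultaneously (a) reach the
`cn_sum_percentile` (default 0.8) of the window's cohort-summed copy number
and gain ≥ `min_cn_gain` (default 1 summed copy over pairs) after
treatment, (b) reach `min_rhmr_recurrence` hypomethylation recurrence, and
(c) carry the required peak evidence (default all of FOXA1 + H3K27ac; an
any-of mode exists because candidate elements can retain pioneer-factor
binding while lacking the primary TF's signal). Interval tracks are binned
with a majority-coverage rule (an interval must cover ≥ 50% of a bin to
contribute), which keeps interval boundaries from bleeding into
barely-touched edge bins and bounds the boundary error of a recovered
region at one bin. Passing bins ≤ `merge_gap` apart merge; merged regions
below `min_width` drop. The evidence values and thresholds used are
attached to each candidate. These quantitative defaults are conservative
config choices standing in for qualitative published criteria; they make
no claim to reproduce any particular published candidate list. Loop
support requires one anchor on the candidate and the other on the promoter
(both anchors on the candidate do not count).

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, at
desk scale:

- **Cohort**: 45 patients × (pre, post) by default; per-sample purity ~
  Uniform(0.2, 0.9); two batches; post samples are the treatment-exposed
  stratum.
- **Genome**: three 5-Mb chromosomes (a full scan stays under a second);
  the X-chromosome analog carries the driver-gene locus layout (enhancer,
  promoter, gene, downstream planted candidate, all inside a 100-kb
  spikeable locus).
- **Copy number**: per-sample Poisson-breakpoint segmentation (mean segment
  250 kb) with Normal(2, 0.4) segment copies. The spiked locus adds +3
  copies in the post sample of 60% of pairs; a TD-backed spike emits a
  duplication SV spanning the locus (with jittered margins), a TD-free
  spike does not. Half the samples carry a +2 baseline amplification (65%
  of those TD-backed), so the locus is also amplified cohort-wide.
- **Mutations**: truncal calls shared within a pair plus private calls;
  VAFs are binomial draws at depth 100 around the purity/copy mixing
  expectation `cf·p / (C_t·p + 2(1−p))` — a clonal heterozygous variant at
  copy 2 has expected VAF p/2. Hotspot specs emit recurrently emerging
  post-only coding mutations in the driver gene.
- **Expression**: NB counts with per-gene log-normal means and dispersions,
  per-patient and per-batch log2 offsets, log-normal library sizes, and
  convex purity mixing of a tumor and a stromal mean profile — purity
  confounding is explicit and tunable because the analyses treat purity as
  a covariate. Designated treatment-responsive genes (log2 fold changes
  −1.5, −1.2, +1.0, +1.0) and the dosage-driven driver gene are modeled as
  well-expressed and tumor-restricted (stromal mean 5% of tumor mean),
  matching the biology of tumor-cell-specific receptor/TF genes; the driver
  gene's tumor-component mean scales with its simulated local copy number.
- **Isoforms**: the driver gene's total counts split across two transcripts
  by Dirichlet-noised mixture weights; one designated converter pair moves
  from a 0.1% to a 60.7% variant fraction, the magnitude of the most
  dramatic splice-variant switch such cohorts exhibit.
- **Tracks**: background hypomethylation/peak intervals plus one planted
  region satisfying every nomination criterion (no driver-TF peak at the
  plant, mirroring a pioneer-factor-only candidate) and a loop from the
  plant to the promoter.
- **Survival**: exponential times with hazard
  h₀·exp(β_t·treated + β_g·low + β_int·treated·low), h₀ = 0.02/month,
  β_t = −0.7, β_g = 0.2, β_int = 0.8 (low-expression tumors losing
  treatment benefit), uniform censoring at 12–72 months, one record per
  post sample.

All randomness derives from one seed via fixed-order sub-streams, so
generating a subset of components reproduces exactly the full run's values
and repeated runs are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mutational signatures and clonal phylogenies,
read-level noise and mapping artifacts, realistic segment-size and
copy-level distributions (no whole-genome doubling, no allele-specific
states), gene–gene expression correlation beyond shared patient/batch
factors, isoform structure beyond a two-transcript split, and cohort-level
ascertainment effects. Green tests certify the statistical machinery under
the model's assumptions, not robustness to everything real cohorts do.

## Problem sizes in the test suite

The statistical guarantees are exercised at sizes chosen to make the checks
sharp yet quick on one CPU: 100-seed spike-recovery and null-calibration
runs of the full 15,000-bin scan at 40 pairs; 100-seed power runs of the
paired NB test at 30 pairs × 200 genes plus one 2,000-gene null; 500
enumeration checks of the exact signed-rank branch; 200 brute-force ssGSEA
instances; 50 random Cox datasets against an independent likelihood
maximizer; 50 nomination fixtures. The pooled null rejection rate of the
scan is compared against the binomial 99% interval at the single-scan bin
count, since bins within a segment are correlated and a genome-wide scan,
not a bin, is the natural replication unit.

## Known limitations

- The NB engine omits moderated effect-size shrinkage, independent
  filtering, and outlier replacement; q-values near the detection floor are
  less stable than those of mature empirical-Bayes engines.
- The AR/NE and subtype scores are transparent approximations of cited
  scoring systems whose exact constructions are not public in formula form;
  absolute score values should not be compared across implementations,
  though the bounded scale and threshold semantics carry over.
- Amplification mechanism classification sees only DUP records; derived
  chains (complex clusters, ecDNA reconstructions) are out of scope.
- The Cox model supports right censoring only — no time-varying covariates,
  interval censoring, or competing risks.
- Batch handling is location-only; scale batch effects pass through.
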