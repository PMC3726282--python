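# Methods

## Study design assumed throughout

Two conditions — unperturbed control and 0.2% (v/v) butanol added at
inoculation — sampled at 24, 48 and 72 h of growth (mid-exponential,
exponential–stationary transition, stationary). Metabolomics uses three
biological replicates per condition and time point (18 samples); RNA-seq
uses single samples per condition and time point except a duplicated
butanol sample at 72 h used to estimate replicate reproducibility. These
defaults are wired into `SimConfig` and the fixture tables and are not
re-derived anywhere.

## Signed fold-change convention

All ratio-valued quantities share one convention: a plain positive ratio
ρ is reported as ρ when ρ ≥ 1 and as −1/ρ otherwise, so defined values
lie in (−∞, −1] ∪ [1, ∞) and "2-fold down" prints as −2.0. For replicate
ratios of abundances that may be zero, detection in only one condition is
carried as ±∞ (an infinitely strong change in that direction) and a
double zero as NaN ("undetected in both"); the ternary coder maps these
to ±1 and 0 respectively. The coder's inequalities are strict — a ratio
of exactly ±1.5 codes 0, i.e. boundary ties fall to the middle bin.

## Transcriptomic layer

- **Read accounting.** The mapping ratio's denominator is qualified reads
  (post quality/ncRNA filtering), not raw reads; per-sample percentages
  are rounded to 2 decimals, the unweighted mean across samples to 1
  decimal, matching the precision the numbers are reported at.
- **RPKM.** Elementwise `C·10⁹/(L·N)`; the inverse transform is provided
  and round-trips exactly in floating point up to rounding.
- **Fold changes** are ratios of replicate-averaged RPKM (arithmetic
  mean; only the 72 h treated point has duplicates under the default
  design). Zeros in either mean trigger a pseudocount — by default half
  the smallest nonzero RPKM in the matrix — added to both sides; with no
  zeros present nothing is added, so fixture tables reproduce exactly.
- **Induction filter.** A gene is induced iff fc ≥ threshold (default
  1.5, inclusive) at every time point. Inclusivity matters: two curated
  genes sit at exactly 1.50 at one time point. Consistently
  down-regulated genes are computed by the mirrored filter but reported
  separately; the induced-gene pipeline ignores them.
- **Replicate correlation** is Pearson's r on log RPKM with the same
  half-minimum pseudocount (configurable, 0 allowed).

## Metabolomic layer

- **Normalization**: value = peak area / internal-standard peak area /
  cell count, scaled by 10⁸ (a typical per-sample cell count) to keep
  magnitudes O(1). Scaling is a display constant; every downstream
  statistic is ratio-based and invariant to it.
- **Ratio cube**: all treated×control replicate pairs per time point —
  the only pairing that yields exactly 9 ratios from 3+3 replicates.
  Replicate order is fixed by sorting, making the cube deterministic.
- **Scoring**: score = Σ of the 9 ternary codes, changed count = number
  of nonzero codes. Qualification uses the changed count (≥ 5 of 9 at
  any time point), not |score| ≥ 5: mixed-sign ratio sets can qualify
  under the literal ≥-5-changed reading. When only a published score
  matrix is available (no underlying ratios), `qualify_from_scores`
  applies max|s| ≥ 5, valid because |s| ≤ changed count always; it is a
  conservative lower bound, and on the packaged table it qualifies all
  46 rows.
- **Clustering** is a data-driven pattern table over the score signs
  (I–V canonical patterns, VI exhaustive catch-all), so alternative
  pattern sets can be supplied without code changes.
- **PCA** centers by default and unit-scales behind a flag (abundances
  are already normalized, so variance weighting is left to the caller);
  component signs are fixed by making each component's largest-magnitude
  loading positive.

## qPCR layer

Standard curves are fit by OLS of Ct on log₁₀(quantity) from ≥ 3 distinct
dilutions; a non-negative slope is rejected as degenerate. Efficiency and
slope are bijective via e = 10^(−1/m) − 1. Technical triplicates are
averaged on the Ct scale before interpolation. Expression ratios divide
target quantities by reference-gene (rnpB) quantities per condition and
report the treated/control quotient in the signed convention; this makes
the ratio invariant to rescaling all quantities of one sample.
Concordance with RNA-seq is direction-only (both ≥ +1 or both ≤ −1) — the
claim being validated is a trend, so no magnitude tolerance is imposed.

## Integration layer

A gene counts as "protein up-regulated" when its proteomic fold change is
≥ 1.5 at at least one of the reported proteomic time points (24 or
48 h) — several reference rows carry a measurement at only one of the
two. Genes absent from the proteomic table are classed unchanged, since
undetected proteins cannot testify either way. The concordance classes
partition the induced set exactly. For the packaged-fixture run the
induced set is the induction filter applied to the union of the curated
induced-gene table and the transcript columns of the transcript/protein
comparison table (the latter's 17 genes all clear the filter); the two
tables overlap in 5 genes, giving 82 induced genes of which 17 class as
both_up. The metabolite–gene link table is curated data shipped as an
editable CSV; the join reports a row only when both sides responded, with
no inference.

## Synthetic data

The generator's defaults are the study conditions above: 500 genes with
10% induced at fold changes uniform in [1.5, 6], 73 metabolites of which
46 are planted across the six cluster patterns (7/7/4/5/3/20), effect
size 3-fold, noise CV 0.1, library sizes 2–6 M mapped reads, gene lengths
200–3000 bp. Where the study reports no variance levels the CVs are free
parameters chosen once as typical of the platforms (RNA-seq biological
CV ≈ 0.1; GC-MS internal-standard CV 0.05; cell-count CV 0.1).

- **Count model**: expression is parameterized in RPKM space so planted
  treated/control RPKM ratios are exact at the mean; counts are the
  inverse-RPKM means, and with noise_cv > 0 they are drawn
  Poisson-gamma (gamma multiplier of CV noise_cv — a negative-binomial-
  like overdispersed model). At noise_cv = 0 the generator emits the
  exact means (then possibly non-integer), which is what makes the
  noiseless-limit recovery properties exact rather than approximate.
- **Abundance model**: multiplicative log-normal with the configured CV
  around strictly positive means; the internal-standard row and cell
  counts vary with their own small CVs so normalization is exercised
  non-trivially, and both are inverted exactly by the normalization step.
- **Cluster VI plants** use (−,−,−) — a pattern no canonical cluster
  claims — so planted truth is consistent with the assignment rule.
- **Randomness**: one seed, split into fixed per-assay streams
  (0 transcriptome, 1 metabolome, 2 qPCR) via `default_rng([stream,
  seed])`; identical configs give byte-identical written outputs.

What the generator does **not** emulate: raw reads or chromatograms,
compositional coupling between genes (each sample's mapped total is drawn,
not summed from a fixed read budget), batch effects, missing-at-random
metabolite dropout, or correlated noise across replicates. Passing
recovery tests therefore demonstrates correctness of the statistics under
the stated noise model, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

Thresholds are compared inclusively for fold changes (≥ 1.5) and strictly
for ternary codes (> 1.5), each matching how the respective rule is
stated. Scores and changed counts are exact integers. Readers of every
table validate type invariants (raw ≥ qualified ≥ mapped, positive
lengths and totals, reserved `IS` row present, known qPCR roles) and
reject offending rows rather than coercing. Degenerate cases raise with
the offending gene/sample named: zero qualified reads (undefined mapping
ratio), zero gene length or mapped total, missing condition at a time
point, constant matrices in PCA, flat dilution series.

## Problem sizes

The default simulated study (500 genes × 7 samples, 73 metabolites × 18
samples, 10 qPCR genes in technical triplicate) mirrors the scale of the
original design and runs in well under a second; the test suite's
exhaustive ternary-score oracle enumerates all 3⁹ = 19 683 code vectors.

## Known limitations

The full-dataset claims of the original study (the 278-gene induced set,
the 0.991 replicate correlation, the 303-protein proteome) depend on raw
reads and spectra that were never deposited; only their curated table
subsets ship as fixtures, and the full counts are not recomputable. The
published per-time-point detection counts read "35, 41 and 38"; the
printed score matrix itself yields 35, 41 and 39 nonzero-score
metabolites, and this package reports the recomputed 39 rather than
silently matching the text. Likewise the text's "48 metabolites" is taken
as the 46 rows the score table actually contains.
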