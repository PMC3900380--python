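# Methods

## The problem

DNA replication in metazoan genomes follows a reproducible temporal
program: when averaged over a cell population, every locus replicates at a
characteristic time in S-phase. Replication timing is measured here on a
smoothed log-ratio (M-value) scale where **higher values mean earlier
replication**. `replichrom` models the quantitative relationship between
this timing signal and the local levels of chromatin features — histone
modifications (HMs) and chromatin-binding proteins (CBPs) — at promoters
and genome-wide, with an emphasis on *combinatorial* (multiplicative
pairwise) feature effects.

## Region universes

Two region sets anchor all quantification:

* **Unique promoters** — fixed-width windows (default 1 kb) centered on
  transcription start sites. A TSS qualifies as unique if no other distinct
  TSS lies within half the window width (±500 bp by default) on the same
  chromosome, regardless of strand; identical TSS positions shared by
  several transcripts are collapsed before the distance test. The ±w/2
  reading of "the 1 kb region flanking the TSS" keeps the uniqueness
  window congruent with the promoter window; the width is a parameter, so
  a ±1 kb rule is one flag away. Uniqueness is symmetric (if A excludes B,
  B excludes A) and the output is invariant to input ordering.
* **Genome bins** — fixed-width tiles (default 10 kb) from position 0 of
  each chromosome; the final partial bin is retained. The packaged dm3
  (BDGP release 5) arm lengths for 2L, 2R, 3L, 3R give exactly 9663 bins
  at 10 kb, which pins the partial-bin convention.

The default chromosome universe is the four large *D. melanogaster*
autosome arms; chromosome 4 (largely heterochromatic) and the X
(dosage-compensated and early-replicating in male cell lines) are excluded
from modeling by default and configurable.

## Feature and timing quantification

Sequencing-based features are scored by a library-normalized log2
enrichment with an integer pseudocount `p ≥ 1` (default 1):

    M_d = log2( (n_S + p) / (c (n_I + p)) ),   c = L_S / L_I

where `n_S`, `n_I` count reads aligning *entirely within* the region for
the ChIP sample and its matched input, and `L_S`, `L_I` are library sizes.
The feature enrichment is the arithmetic mean of `M_d` over replicates.
The pseudocount is added to both counts and the library ratio is applied
to the input count; this placement makes the score exactly antisymmetric
under swapping sample and input, the property the test suite asserts.

Array-based features and replication timing are the unweighted mean of
probe values lying entirely within the region; regions with no covered
probe are missing and dropped (with a log message) at matrix assembly.

QC clustering of feature profiles uses the correlation dissimilarity
`d = (1 − ρ)/2 ∈ [0, 1]` (`1 − ρ` available as an option) with average
linkage by default; columns are name-sorted first so leaf order is
deterministic under ties.

## The modeling protocol

The core model is an L1-penalized (Lasso) linear regression of timing on
an interaction-expanded design:

1. **Expansion.** Main-effect columns are standardized; order-2 (optionally
   order-3) interaction terms are products of standardized mains,
   re-standardized. Named feature groups control which products are formed
   (within-group pairs, or pooled across groups), which expresses recipes
   such as "pairwise HM interactions plus CBP main effects". No
   self-powers; term names are `A:B` products of their parents.
2. **Split.** Regions are randomly partitioned into training and test sets
   (default train fraction 0.662, mirroring a 5000/2552-style split).
3. **Path and cross-validation.** A single geometric λ-path (default 100
   values, three decades below λ_max) is computed on the training design
   and shared by all ten folds. The top of the path is the largest
   fold-level λ_max so the path provably starts at the all-zero model in
   every fold. Each fold fits the full path; the per-λ cross-validated
   model is the arithmetic mean of the ten fold coefficient vectors
   (averaging coefficients rather than predictions — a refit-free choice
   consistent with the protocol's "averaged models"; a refit option is a
   natural extension but is not the default). CV-MSE at each λ is the mean
   validation MSE over folds; λ* is the strict minimizer (no
   one-standard-error rule), ties broken toward the larger λ.
4. **Accuracy.** Pearson correlation between measured and predicted timing
   on the held-out test set. Residuals are measured − predicted.

Coefficients are reported on the standardized scale. Standardization is
always on (Lasso is scale-sensitive); the stored per-term means and SDs
travel with the fit, so applying a promoter-trained model to genome bins
rebuilds the design with the *training* parameters.

**Reported support.** Fold-averaged coefficient vectors are dense at the
noise level: a term selected in one fold of ten keeps a tiny averaged
weight, so the strict nonzero set is the union of the fold supports. The
reported support therefore applies a 1% relative cutoff on the largest
absolute coefficient (measured separation in simulations: true terms carry
≥50% of the top coefficient, fold-averaging residue ≤0.1%); `rel_tol=0`
returns the strict set.

## Feature importance and simplified models

* **λ-path scan** — evaluate held-out accuracy at every λ of the fitted
  path; among models retaining at least `min_fraction` of the full-model
  accuracy return the one with fewest nonzero terms (ties → larger λ).
  The all-zero model has undefined correlation and never qualifies.
  The default fraction is 0.75; 0.70 appears in some uses and both are
  exposed.
* **Bootstrap-Lasso stability selection** — `B` bootstrap resamples (with
  replacement, size n), each fitted along a fixed decreasing λ-grid from
  λ_max (empty model) to 10⁻³·λ_max (an almost-full model; both endpoints
  configurable — note the lower endpoint materially shifts *absolute*
  selection probabilities, while the true/null *ranking* is robust to it).
  A term's selection probability is its nonzero count over all (resample,
  λ) fits divided by B·G; the bookkeeping is exact (p·B·G is an integer).
  z-scores are mean/SD of the term's coefficient across bootstraps at the
  prediction λ (the λ* of a cross-validated fit on the full data unless
  supplied); this z-score definition is a pinned convention.
* **Feature-exclusion significance** — for each of `B` bootstrap samples,
  fit the full model and the model lacking *all* terms involving the
  chosen feature on the same train/test split, and compare the two
  held-out-accuracy samples with a two-sided Wilcoxon rank-sum test.
  Because both models are fitted on the same bootstrap samples the two
  accuracy samples are strongly positively correlated; under a null
  feature they are nearly identical vectors and the rank-sum statistic
  sits at its null mean almost deterministically. The test is therefore
  *radically conservative* under the null (p-values pile up near 1, far
  from uniform) while remaining sensitive to real exclusions — a property
  users should keep in mind when interpreting non-significant results.
  Degenerate (constant-prediction) fits contribute accuracy 0.
* **Exhaustive best-subset search** — ordinary least squares on every
  feature subset up to size 4 (OLS has no tuning parameter, so a plain
  train/test protocol without inner CV), ranked by held-out Pearson
  accuracy, with BIC = n·ln(RSS/n) + (k+1)·ln(n) on the training fit
  (Gaussian likelihood, intercept counted, error variance profiled out —
  a pinned convention). A guard refuses pools whose projected model count
  exceeds a limit unless forced; for a 94-feature pool the k = 1..4 counts
  are 94, 4 371, 134 044 and 3 049 501 (3 188 010 in total). Appearance
  frequencies are computed over models reaching a stated fraction
  (default 0.6) of the full-model accuracy.

## Genome-wide stage

* **Prediction** — the promoter-trained fit is applied to the bin feature
  matrix; interaction terms and standardization are rebuilt from the fit's
  stored parameters. Accuracy is reported overall and per chromosome.
* **Smoothing** — the smooth (scaling-coefficient) component of an
  undecimated wavelet multiresolution analysis at level J = 2 with the
  8-tap least-asymmetric filter (pywt `sym4`, coefficient-identical to the
  classical "la8") and reflection boundaries. Constants are reproduced to
  machine precision and the transform commutes with affine maps.
* **Segmentation** — recursive binary segmentation: at each segment the
  maximal two-sample t statistic over candidate splits is compared with
  its permutation distribution (default 1000 permutations, α = 0.01,
  minimum segment 3 bins), and significant splits are recursed — the
  desk-scale operationalization of circular binary segmentation.
  Timing transition regions (TTRs) are windows of ±halfwidth (default
  15 kb) around each boundary — on 10 kb bins, the boundary bin plus one
  flanking bin per side, i.e. 3 bins — with overlapping windows merged;
  domains are the complement, so TTRs and domains partition the bins.
  Segmentation is invariant to adding a constant to the profile.
* **Gene density** — a two-state hidden Markov model with Poisson
  emissions (Poisson chosen over a Gaussian on densities because the
  per-bin input is a count), fitted by Baum-Welch with seeded restarts and
  decoded by Viterbi; the state with the larger emission mean is labeled
  gene-dense, making labels invariant to initialization. All-equal counts
  short-circuit to a flagged single-state labeling.
* **Stratified accuracy** — Pearson correlation within each region class
  (domain/TTR, gene-dense/poor, per arm); classes with fewer than 3 bins
  report NaN.

## Cross-cell-type stage

Both cell types are restricted to a common feature list (the packaged
list has the 21 histone modifications profiled in both cell lines) and to
co-scored regions. One interaction-expanded model is fitted per cell type
on a shared split, and each is also applied to the other type's test
regions (matched accuracy is expected to exceed unmatched). Differential
timing Δt = t_A − t_B is modeled from differential marks ΔX = X_A − X_B
with the standard protocol; since timing is a log-ratio, Δt *is* the log
fold change, and differentially replicating promoters (DRPs) are regions
with |Δt| ≥ δ (δ ∈ {0.8, 0.9, 1.0} by default; the absolute value is used
so all four early/late quadrants can qualify). Δ-operators are
antisymmetric under swapping the cell types and DRP sets are nested in δ.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with known
ground truth:

* **Promoter datasets** — standard-normal features in block-correlated
  groups (a shared Gaussian latent factor per block of 4 consecutive
  features within each class gives within-block correlation `block_corr`,
  default 0.3 — mimicking the correlated HM families that motivate
  stability selection); a sparse linear response over standardized
  features with multiplicative interaction terms plus Gaussian noise
  (defaults: 3 main + 2 interaction effects over 12 HMs and 8 CBPs). The
  reported `oracle_r2` is the realized 1 − var(ε)/var(y) — the ceiling any
  model can reach on that draw; `noise_sd_for_r2` calibrates the noise to
  a target R² from the simulated signal variance.
* **Count tracks** — Poisson input counts at a given rate and Poisson
  sample counts at rate `2^M · input_rate · L_S/L_I`, so the enrichment
  score recovers the target M in expectation with bias vanishing as rates
  grow.
* **Genome profiles** — piecewise-constant latent timing over
  geometrically distributed domain lengths with linear ramps of half-width
  `ttr_halfwidth_bins` at boundaries; features are noisy linear encodings
  of the latent timing plus pure-noise nuisance columns; gene density is a
  two-state Markov chain (stay probability 0.97) emitting Poisson counts
  (means 0.3 / 4.0). Per-bin truth labels record domain ids, boundary
  positions and the density state.
* **Cell pairs** — cell B reuses cell A's features and coefficients;
  divergence enters through the *levels* of the features underlying the
  first `n_divergent` true terms (shifted by `divergence_scale` times a
  fresh normal draw per region), plus a small (0.05 SD) everywhere-on
  wobble so ΔX is never exactly constant. This is the construction under
  which all the intended differential behaviors hold simultaneously:
  with zero divergence Δt is essentially pure noise (differential accuracy
  ≈ 0), with divergence the conditional mean of Δt is linear in the
  divergent terms of ΔX, and the two timing profiles remain highly
  correlated when divergence is small. Divergence expressed through
  coefficients with shared feature values would instead make ΔX constant
  (a degenerate differential design), which is why the feature-level
  formulation was chosen.

What the generator does *not* emulate: spatial autocorrelation of
chromatin marks along the genome at promoter scale, heavy-tailed or
heteroskedastic assay noise, probe-level array structure, mappability and
copy-number artifacts, and any causal structure between marks. Passing
tests therefore demonstrate that the *procedures* behave as specified
under their own assumptions, not that real chromatin data satisfy those
assumptions. The Gaussian noise model in particular is a modeling
convenience, not a claim about the assay.

## Numerical choices

* Lasso solving via scikit-learn coordinate descent with objective
  `(1/2n)·RSS + λ‖β‖₁`; λ_max = max|⟨x_j, y − ȳ⟩|/n. Solver tolerance
  1e-6 (1e-10 in oracle comparisons). An independent check confirms the
  solver's penalized objective beats a 21³ coefficient grid on small
  instances at every λ.
* Intercepts are unpenalized fold-train means of the response.
* Constant responses return a flagged zero model; zero-variance design
  columns get unit SD in standardization (their coefficients are then
  never selected).
* Permutation p-values use the add-one correction (min p = 1/(n_perm+1)).
* All randomness flows from a single integer seed through named
  substreams (BLAKE2-hashed stream names spawning a `SeedSequence`), so
  any stage re-run in isolation reproduces its output bit for bit.

## Problem sizes used in the shipped evaluation

The bundled evaluation (test suite and `scripts/acceptance.py`) exercises
the pipeline at desk scale as the package's own benchmark conditions:
promoter recovery at n = 5000 regions, 20 features, order-2 expansion
(210 terms), oracle R² = 0.5, 20 independent seeds, with stability
selection at B = 30 bootstraps over a 50-value grid; the simplified-model
scan on a 12-feature two-dominant construction (n = 1500, 20 seeds); the
exclusion test at n = 400/B = 20 (power) and n = 160/B = 16 over 200
replicates (null calibration); segmentation on 100-bin step profiles over
100 replicates; smoothing and HMM labeling over 20 seeds; and the
cross-cell-type stage at n = 1000 with B = 15 over 20 seeds.

## Known limitations

* The enrichment-score pseudocount placement and the correlation
  dissimilarity are pinned conventions chosen for their invariance
  properties (antisymmetry; boundedness); alternative placements exist.
* CV-minimizing λ overselects by design; the simplified-model and
  stability procedures, not λ* itself, are the intended route to small
  models.
* The exclusion test's null conservativeness (above) means its p-values
  are not calibrated; they are useful as a strong-evidence screen, not as
  uniform-null p-values.
* The segmentation is a desk-scale stand-in for the full circular variant:
  it tests single splits rather than circular (i, j) arcs, which mainly
  affects detection of small interior segments.
* Exhaustive search beyond 4 features is combinatorially guarded, not
  parallelized.
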