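# Methods

This note records the models, estimators and numerical conventions behind
`micronorm`, the choices made where several defensible options existed, and
what the synthetic benchmarks do and do not establish about real data.

## Data model

A count table is an integer taxa × samples matrix; library size N_j is
always the live column sum, never cached.  Two-group tests require exactly
two labels and fail fast on missing labels.  Quantiles everywhere
(low-depth filtering, logUQ/CSS divisors, replicate upper quartiles) are
linear-interpolation (type-7) quantiles, the numpy default; the flavor only
moves borderline samples, and the convention is recorded once here rather
than per call.  Low-depth filtering drops samples strictly below the
threshold quantile; ties at the threshold are kept.

## Normalization

All scaling methods rescale by a common constant C = median library size so
their outputs live on a comparable "counts" scale; C is recorded in each
result's parameters.

* **Proportion** — column / column sum; rejects all-zero samples.
* **Rarefy** — multivariate hypergeometric draw per column to a common
  depth (exactly the column when depth equals its total); with-replacement
  multinomial draws are available for reproducing older pipelines.
  Shallower samples are excluded and listed.
* **logUQ** — per-sample 75th percentile of the *nonzero* counts as the
  divisor, then log2(x·C/s_j + 1).  On ~90%-sparse data the raw 75th
  percentile is 0 for most samples, which would be degenerate; the
  nonzero-only choice is flagged in the output parameters.
* **CSS** — divisor is the sum of each sample's counts up to an adaptive
  quantile l̂.  Per-sample quantile curves (over nonzero counts, grid
  0.01-0.99) are compared to the across-sample median curve; l̂ is the first
  grid point (≥ 0.25) where the median relative deviation exceeds its
  running minimum by more than 10% — i.e. where the distributions stop
  being mutually invariant.  Degenerate tables fall back to the median
  (0.5) with a warning.  Fixing the quantile at 1.0 reduces CSS to
  proportion scaling times C, which is asserted in the tests.
* **DESeq size factors** — median of per-taxon ratios to geometric means,
  over taxa positive in every sample; factors rescaled to geometric mean 1.
  When no taxon is positive everywhere (common in sparse tables) a
  pseudocount route over all taxa is used and recorded.
* **DESeqVS** — size-factor scaling followed by a glog variance-stabilizing
  transform for a *common* NB dispersion estimated by moments
  (median over taxa of (v−m)/m²):
  f(x) = log2((2αx + 1 + 2√(αx(1+αx))) / 4α), which is affine-calibrated so
  f(4x) − f(x) → 2, i.e. log2 behavior at large counts.  With α > 1/4 the
  transform is negative near zero; negatives are clamped to 0 by default,
  which makes the output legal for non-Euclidean ecological distances at
  the price of erasing many rare taxa — both behaviors are asserted.  A
  spline mean-variance fit would add flexibility but not change the
  contract (variance roughly independent of the mean); the closed form was
  preferred for transparency.
* **TMM** — reference sample = the one whose upper-quartile/library-size is
  closest to the mean of that statistic; M and A values over taxa positive
  in both; two-sided trimming of 30% (M) and 5% (A) per tail — the
  method's canonical defaults, exposed as parameters; inverse-asymptotic-
  variance weights; factors rescaled to geometric mean 1.

## Beta diversity

Binary metrics use presence = value > 0 *after* normalization, so clamped
variance stabilization legitimately zeroes rare taxa.  Weighted UniFrac is
the normalized variant (bounded [0,1]) so ordinations are comparable across
metrics.  UniFrac is computed by post-order accumulation of per-branch
descendant abundances.

PCoA is the Gower-centered eigendecomposition; negative eigenvalues are
reported, never corrected, and coordinate axes use positive eigenvalues
only, so Euclidean input is reconstructed exactly (asserted at 1e-9).

PERMANOVA partitions the Gower-centered total SS by type-I *sequential*
sums of squares over ordered model terms (cumulative QR projections), so R²
attribution deliberately depends on term order: entering library size first
absorbs depth artifacts before the biological term is assessed.  P-values
permute sample identities (rows/columns of the Gower matrix) with the
(b+1)/(m+1) estimator so p is never exactly zero; residualized permutation
schemes are future work.

PAM uses deterministic greedy BUILD followed by best-improvement SWAP, plus
seeded random restarts (default 10); on 8-point fixtures the result matches
exhaustive medoid enumeration.  Clustering accuracy maximizes over
cluster-label assignments (Hungarian matching), and the penalized variant
adds dropped samples to the denominator as misclassified — with the bottom
15% of 40 samples dropped, a perfect clustering scores exactly 34/40.

## Differential abundance tests

All tests return per-taxon statistics, raw p, BH q (step-up, NaN excluded
from the ranking rather than imputed), and the called set at α = 0.05.

* **Mann-Whitney** — mid-ranks; exact p when both groups ≤ 8 samples and no
  ties, else the normal approximation with tie correction.
* **Welch t** — Satterthwaite df; both-groups-constant taxa get p = 1.
* **ANCOM** — every pairwise additive log-ratio (pseudocount 0.001 added to
  all counts, preserving order), Mann-Whitney per pair, BH within each
  taxon's m−1 p-values (a global-scope option exists), W = rejection count.
  Taxa detected in fewer than 10% of samples (min 2) are excluded from
  testing *and* from the reference set: a log-ratio against an essentially
  never-observed taxon collapses to the taxon's own abundance over the
  pseudocount, so any global compositional shift would register as a
  rejection against every such "partner" — with a 90%-sparse table that
  artifact alone drives the false discovery rate above 0.5.  Final calls:
  W ≥ 0.7·(m−1) by default, or the largest gap in the upper 30% of the
  sorted-W curve ("empirical" mode); both the cutoff and the mode are
  recorded.  Both are approximations to calling from the empirical W
  distribution, and on the compositional benchmark they agree.
* **NB GLM** — median-of-ratios size factors unless supplied.  Per-taxon
  dispersions by moments on size-factor-scaled counts, blended 50/50 on the
  log scale with a non-negative-least-squares trend a₀/mean + a₁; the blend
  weight is exposed, since more trend shrinkage is what separates
  anticonservative from conservative NB testing.  Wald mode fits per-group
  means by a vectorized fixed-point iteration of the NB score equation with
  size-factor offsets, takes the expected-information SE, and (optionally)
  shrinks log-fold changes with a zero-centered normal prior whose variance
  is the excess spread of the unshrunk estimates.  Exact mode conditions on
  the total of the size-factor-equalized group sums, with the sum of a
  group's counts treated as NB with size n_g/α; the two-sided p sums all
  splits no more probable than the observed one (full enumeration up to
  totals of 4000, a matched normal approximation beyond).  All-zero taxa
  get p = NaN.
* **voom** — log2 counts-per-million with TMM effective library sizes and
  offset 0.5; lowess of √sd on mean log-count supplies observation weights
  (predicted sd⁻⁴); weighted group contrast tested with an empirical-Bayes
  moderated t whose prior df and scale come from moments of log sample
  variances (trigamma inversion by Newton).
* **Zero-inflated Gaussian / lognormal** — mixture of a point mass at zero
  and a Gaussian on log2(count+1), with a per-taxon mean model
  (intercept + group + log2 CSS-scale covariate, so depth effects on the
  observed values are absorbed by a fitted coefficient) and a zero-mass
  probability that is logistic in log library size, shared across taxa.
  EM with exact M-steps (weighted least squares; warm-started step-halving
  Newton for the logistic), so the log-likelihood trace is non-decreasing
  and asserted as such.  Three guards keep the mixture honest: zeros start
  fully assigned to the point mass, iterations default to 10, and the
  Gaussian variance is floored at 0.25 on the log2 scale — without them the
  Gaussian collapses onto the zero spike and chance singleton detections in
  one group masquerade as clean effects.  Variance moderation uses
  per-taxon effective df with the prior fitted on adequately detected taxa;
  taxa detected in fewer than 2 samples are not tested.  The model's
  defining dependence on library size cuts both ways, and both sides are
  under test: on even-depth random nulls its type-I error is near nominal,
  but when groups are confounded with depth it attributes depth artifacts
  to the group effect and its false-positive rate inflates well beyond any
  other method's — running it on rarefied input is allowed but flagged,
  since rarefying destroys the information its zero model keys on.

## Simulation designs

**Templates.**  A synthetic ecosystem is a proportion vector with three
bands, mirroring the mass structure that a ~90% zero fraction forces on a
real table: an observable lognormal block (σ = 1.2, so the dominant taxon
holds roughly 5-15% of reads) carrying almost all the mass, a marginal band
log-uniform across the detection limit (0.05-5 expected reads at the
reference depth), and a long tail pinned far below detection (~0.01
expected reads per taxon).  The observable fraction is tuned by bisection
against the analytic zero fraction mean_i exp(−N·π_i) at the reference
depth (2000); unattainable targets warn and use the nearest attainable
value.  Everything is deterministic given the seed.  Templates can also be
fitted from data: pooled multinomial proportions; Dirichlet-multinomial
overdispersion θ by moments on across-sample proportion variances (recovered
within 20% from 500 samples in the tests); per-taxon gamma-Poisson shapes
and rates from depth-scaled means and variances, with a flagged Poisson
limit when variance ≤ mean (shapes recovered within 25%).

**Library sizes** are lognormal around the target median N_L with spread
0.5 on the log scale (~9× range over the central 95%), recorded per
dataset; count draws are multinomial, Dirichlet-multinomial
(concentration (1−θ)/θ · π), or per-taxon gamma-Poisson with the gamma mean
scaled by the drawn depth.  At θ → 0 and shape → ∞ both overdispersed
families reproduce multinomial sensitivity and FDR within Monte-Carlo error
(asserted on matched seeds).

**Truth selection.**  True-positive taxa are drawn only from taxa
observable at the target depth (π ≥ 1/N_L; if that pool is smaller than
twice the requested count, the most abundant taxa stand in), because a
taxon that is never sequenced cannot carry a detectable signal and real
benchmark constructions inflate *observed* taxa.  The balanced design
stratifies the picks by abundance quartile within the pool.  The
compositional design instead makes the truth *mass-representative*:
raising "10% of taxa" should raise roughly 10% of the community's mass, as
a random draw from a real table would, so observable taxa are accepted
under a mass budget equal to the truth fraction and the count is padded
from the rare tail.

**Balanced design.**  The truth set is split into two halves; one half is
raised `fold_change`-fold in group 1's ecosystem and the other in group
2's, with the second multiplier adjusted so both renormalizers are *exactly*
equal.  Consequently the set of taxa whose ecosystem proportions differ
between groups is exactly the recorded truth — differential abundance and
differential relative abundance coincide, which is asserted symbolically on
the vectors.  A legacy "original" mode inflates one group's counts after
sampling, reproducing the renormalization artifact of older benchmarks.

**Compositional design.**  Fold changes apply to one group's ecosystem
abundances only; after renormalization every non-truth taxon's relative
abundance strictly decreases in that group (asserted), so scoring against
the ecosystem-level truth measures exactly the false discoveries that
relative-abundance tests cannot avoid.

**Null splits.**  Random splits of a single biological group, or
depth-uneven splits (deepest n vs the depth-sorted window whose mean best
approximates a 10× ratio); the truth set is empty, so every call is a false
positive.

## Evaluation conventions

Sensitivity is |called ∩ truth| / |truth| (NaN when the truth is empty);
FDR is |called \ truth| / |called| and defined as 0 when nothing is called,
so no-call replicates enter averages instead of propagating NA (an
NA-propagating mode is a one-line change in `confusion_metrics` callers).
Replicates aggregate as medians with type-7 upper quartiles.  Effect sizes
for the CDF view are |Cohen's d| on relative abundances with zero-variance
taxa skipped and counted.  Grid cells get seeds from a CRC32 hash of the
base seed and the cell parameters, so reordering the grid does not change
any cell's data; failed cells are recorded with their error and the run
continues, and an output directory acts as a JSON cell cache for resumable
runs.

Default study conditions: clustering in sets of 40 samples across library
sizes 1000-10,000 and eight mixing proportions; differential abundance with
a fold-change grid {1.5, 2, 5, 10, 15}, 10% true positives, N_L = 2000,
three replicates per cell; null splits with 3/20/100 samples per group.

## What the benchmarks do and do not show

The generators emulate the statistical shape of marker-gene surveys —
heavy-tailed abundances, ~90% zeros, ~10× library-size spread, distinct
community templates — but not sequencing error, chimeras, taxon-taxon
ecological correlation beyond the compositional constraint, or time-series
structure.  Conclusions transfer to real data only insofar as those shapes
drive the artifact under study.

Two honest limitations of the current defaults are worth stating.  First,
under a scalar-θ Dirichlet-multinomial the per-taxon NB dispersions lie
essentially on the a₀/mean trend, so the trend-moderated dispersion
estimator is unbiased there and the NB tests remain calibrated even at
n = 100 per group — heterogeneous real-data dispersion profiles, where
trend moderation systematically underestimates outlying taxa, are what this
simulation family cannot represent.  Second, the zero-inflated Gaussian's
structural-zero treatment trades sensitivity for calibration: chance
singleton detections are no longer called, but genuinely rare
differentially abundant taxa are harder for it to see than for the rank
tests.
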