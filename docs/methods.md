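# Methods

## Design and estimability

The experiment is clustered: each individual fish contributes one sample
per brain part, so the six samples of an individual share biological and
technical idiosyncrasies. The design matrix therefore carries one fixed
indicator per individual. Because every individual belongs to exactly one
species, these indicators absorb the species main effect — which is also
confounded with housing (one aquarium per species) — so species main
effects are deliberately not estimable and never tested. The remaining
columns are brain-part effects shared between species (reference part
pinned at zero; the first observed part by default) and, when two species
are present, interaction columns holding the second species' part-effect
offsets. On the full 60-sample layout this gives 10 + 5 + 5 = 20 columns
of full rank; results are invariant to the reference-part choice (checked
by test), and a rank-deficient layout after sample dropout raises with
the names of the non-estimable coefficients.

Two contrast families are built on this design: 12 within-species
contrasts (each part against the mean of the other five, per species) and
15 interaction contrasts (the part-pair difference in species 1 minus the
same difference in species 2, one per unordered pair).

## NB quasi-likelihood inference

Counts are modelled NB with a log link and offsets equal to log TMM-
effective library sizes. Fitting is iteratively reweighted least squares,
batched across genes (the per-gene normal equations are solved as one
stacked linear-algebra call), with step halving on deviance increases,
relative-deviance tolerance 1e-8 and at most 50 iterations; non-converged
or all-zero genes are flagged, not raised. Coefficients live on the
natural-log scale internally and are reported in log2; thresholds stated
in log2 units are converted by ln 2.

Dispersion estimation proceeds in three steps:

1. **Gene-wise NB dispersion** maximises the Cox–Reid adjusted profile
   likelihood (profile likelihood minus half the log-determinant of the
   weighted information) over an 18-point log-spaced grid from 1e-4 to
   ~5, refined by quadratic interpolation in log dispersion.
2. **Trend**: a robust lowess (fraction 0.4, 3 robustness iterations) of
   log gene-wise dispersion on average log2-cpm; the trended value is the
   dispersion used by all downstream fits. With fewer than 10 genes the
   trend degenerates to the median (a `common_only` switch forces this
   for testing).
3. **QL squeezing**: the per-gene quasi-dispersion s² = residual deviance
   / residual df at the trended dispersion is squeezed toward a common
   value by moment-matching a scaled-F prior on the log scale (mean and
   variance of log s² against digamma/trigamma moments; the trigamma
   inverse solved by Newton). When the observed spread does not exceed
   the sampling spread the prior df is infinite and the common value is
   the geometric mean of the observed s², so identical inputs pass
   through unchanged.

Hypotheses are tested with QL F-statistics: F = (deviance of the
constrained refit − full deviance) / (df₁ · s̃²), with denominator df
d₀ + (n − p) (χ² limit when d₀ is infinite). Constrained refits project
the design onto the orthogonal complement of the contrast rows, which
handles arbitrary (possibly rank-deficient) contrast matrices without
hand reparametrization; df₁ is the contrast rank.

## Stage-wise testing

Stage I screens each gene's family-wide global null with the omnibus QL F
test of the stacked contrast matrix, adjusted by Benjamini–Hochberg and
thresholded at α = 0.05. Stage II Holm-adjusts the per-contrast p-values
within each screened gene and flags those at or below α·R/G (R screened
of G tested genes) — the screening-adjusted level that makes the two
stages control the overall gene-level FDR at α. The two families are
screened separately by default; a `pool_families` switch screens them
jointly, since the original description of the procedure leaves this
open. The α·R/G rule itself is likewise one documented convention among
minor variants; it is the one implemented here and exercised by the
error-rate benchmarks.

## Threshold and equivalence tests

The threshold test of H₀: |log₂FC| ≤ τ (default τ = 2) uses the QL
standard error of the contrast from the scaled inverse information; the
p-value sums the upper tails of the statistic shifted to the nearer and
farther boundary, on d₀ + (n−p) df. At τ = 0 it reduces exactly to the
two-sided test. Multiplicity follows the screening stage: BH across
screened genes within each contrast.

TOST equivalence against Δ = 2 log₂ units reparametrizes the design so
the contrast is a single coefficient, refits the null model with the
sample-wise offset shifted by ∓Δ·ln 2 along that coefficient's column,
and converts each deviance difference to a one-sided p through a signed
√F treated as t on d₀ + (n−p) df; the TOST p is the maximum of the two
sides. Equivalence is declared per contrast by BH within the contrast at
5%, and globally by BH across genes on the within-gene maximum p over all
15 contrasts. The default equivalence universe is all filtered genes
(configurable to screened genes only).

## Competitive gene-set testing

The gene-level statistic is a signed normal-equivalent score from the
two-sided per-contrast p-value and the sign of the fold change. A set is
compared to the rest of the universe by a two-sample t statistic on G−2
df whose in-set variance contribution is inflated by VIF = 1 + (m−1)ρ̄,
where ρ̄ is the mean pairwise correlation of the set genes' residuals
after projection onto the design's residual space (rows normalised to
unit length; the mean correlation computed from the squared norm of the
row sum). The VIF is floored at 1. Sets are intersected with the
universe; singletons are reported descriptively, never tested. The
enrichment workflow uses the union of confirmed DE genes as the universe,
ranks by the part's contrast statistic per species, applies BH per
species × part table, and reports the sets significant in both species
per part plus the top upregulated sets shared by both species, alongside
the count of set members uniquely DE in that part (confirmed in exactly
one of the six part contrasts).

## Synthetic data

The generator mirrors the target design: 2 species × 5 individuals × 6
parts (optionally dropping one random sample, as a low-depth sample would
be dropped in practice), log-normal library sizes with median 1e6 and
log-sd 0.4 (spanning roughly 3×10⁵–3×10⁶), baseline log2-cpm ~ N(5, 2²)
so the 15-cpm filter bites realistically, gene-wise NB dispersions ~
Gamma(4, 0.025) (mean 0.1, bulk 0.05–0.2), per-individual effects ~
N(0, 0.1²) log2 units shared by all six samples of the individual (the
clustering the fixed individual columns must absorb), a 10% fraction of
genes with a single-part effect of |log₂FC| ~ U(1, 3) shared by both
species, and a 5% fraction with a species-2-only part effect of |log₂FC|
~ U(2.5, 4) — kept away from the Δ = 2 boundary so equivalence truth
labels are unambiguous; boundary-mass configurations (used by the size
benchmarks) set the interaction magnitude exactly to Δ. Reported library
sizes are the drawn sequencing depths, not column sums, because the
simulated genes are a subset of a transcriptome. Each gene consumes its
own counter-derived RNG stream from the root seed, so increasing the gene
count extends an existing simulation without reshuffling.

What the generator does *not* emulate: mapping artefacts, 3′-bias or
gene-length effects (irrelevant for 3′ counting), correlated co-expression
modules (so enrichment calibration uses its own correlated Gaussian
benchmark), outlier samples, and GC/batch trends. Passing tests therefore
demonstrate correctness of the procedures under the declared NB model,
not robustness to every artefact of real libraries.

Scoring: gene-level FDR is the fraction of flagged genes (screened with
at least one confirmed contrast) that are truly globally null; power the
fraction of truly non-null genes flagged; genes filtered out before
testing count as unflagged. Recovery reports bias and RMSE of estimated
log₂FC by integer stratum of the true absolute effect.

## Benchmark problem sizes

The packaged benchmarks use 20 replicates of 2000 genes for the FDR
experiment, 800 genes for the boundary-size studies, 500 genes at high
expression for recovery, 400 Monte-Carlo replicates for the gene-set
calibration, and a 1500-gene end-to-end pipeline run — sizes at which the
Monte-Carlo error bands quoted in the tests are meaningful while a full
suite run stays in the minutes range. The boundary-size check across 15
contrasts applies a 2·MC-SE band to the pooled rate and a 3·MC-SE band
per contrast, since 15 simultaneous 2σ binomial checks would fail by
chance about half the time even for an exactly calibrated test.

## Known limitations

- The QL F-test relies on deviance-based quasi-dispersions; at very low
  counts its size can drift slightly either side of nominal (null
  p-values are uniform to a KS statistic of a few percent at the
  benchmark sizes, not exactly uniform).
- Fixed individual effects cost 10 df; with fewer parts per individual
  the design approaches saturation and the residual df check will raise.
- The MDS "top genes" distance is available in two variants (per-pair
  leading log-FC, default, or one common top-variance set) because the
  two conventions genuinely differ; the choice is a config switch.
- GO-style set collections are taken as flat gene → set mappings; no
  ontology-graph propagation is performed.
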