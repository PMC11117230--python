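# Methods

`biphasic` implements a two-stage phylomorphometric analysis for
organisms with complex life cycles: a larval shape space built from 2D
landmark configurations, an adult shape space built from linear
measurements, and a battery of tree-aware statistics asking whether
the two stages evolve together or independently (the adaptive
decoupling question). This note records the statistical models, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Shape spaces

**Landmarks (larval).** Generalized Procrustes Analysis translates
each configuration to its centroid, scales it to unit centroid size,
and iteratively rotates it to the running consensus using the
closed-form orthogonal solution with the determinant forced positive
(no reflections, preserving left/right anatomical identity). The
consensus is renormalized to unit centroid size every round, so the
aligned coordinates are full-Procrustes coordinates; no tangent-space
projection is applied, which is accurate for the small shape variation
this workflow targets. Convergence tolerance: RMS consensus change
below 1e-10 (default), normally reached in 2-4 iterations. Species
with 1-2 digitized specimens are handled by aligning all specimens
together and averaging aligned coordinates per species.

**Pairwise shape distance** is the partial Procrustes distance: both
configurations centered and scaled to unit centroid size, optimal
rotation applied, root summed squared difference returned.

**Measurements (adult).** The log-shape-ratio transform divides each
species' measurements by their geometric mean and takes natural logs;
rows sum to zero and the representation is invariant to specimen
scale. Snout-vent length is excluded from the geometric mean and
carried separately as ln(SVL), the size variable for adult allometry.

**Missing measurements** are imputed with an iterative PCA scheme:
columns standardized, missing cells initialized at the column mean,
then refilled from a rank-`q` SVD reconstruction until the imputed
values move less than `tol` (1e-8 RMS, capped at 1000 iterations with
a warning flag on non-convergence). Observed cells are never altered.
Default rank `q = 2`, configurable; two components capture a size axis
plus one shape contrast, which is the structure the generator builds
and a common choice for morphometric tables of ~10 variables. Because
the reconstruction is unconstrained, an imputed length can
occasionally fall non-positive; such cells are floored at half the
smallest observed value in their column (logged), keeping the table a
valid set of physical lengths.

**Disparity** is Procrustes variance: the mean squared (Euclidean)
distance of rows to their group mean, divisor `n`. The same divisor is
used in the disparity-through-time profile so the two disparity
notions agree at the present.

## Morphospaces and permutation inference

PCA is covariance-based on column-centered data; components are
ordered by variance, and each component's largest-magnitude loading is
made positive (a deterministic sign convention). Explained-variance
fractions are taken against total variance, so they sum to 1 over the
retained rank.

Procrustes ANOVA uses sequential (type-I) sums of squares: the trace
of the difference of residual cross-products between nested
least-squares fits, in the user-given term order. Significance uses
residual randomization (RRPP): for each term, residuals of that term's
reduced model are row-permuted, the term F recomputed, and
`p = (count >= observed + 1)/(nperm + 1)`. The effect size Z is the
standardized position of the observed statistic within the
log-transformed permutation distribution (observed included), an
approximate convention. Because the nested projectors are orthogonal,
the reduced-model fitted part cancels from both the term SS and the
full-model residual SS, which is what makes the permutation loop
cheap. Default 9999 permutations.

Allometry fits shape ~ ln(size) x group sequentially (size, group,
interaction — the order the allometry table prints). The regression
score is the projection of centered shapes onto the common size
coefficient vector; the predicted-shape PC1 is the first principal
component of the fitted values from the size-by-group model, which
preserves family-specific allometric trends in one axis. Per-group
simple regressions report R² with an RRPP p whose reduced model is the
intercept. The developmental-stage factor is carried in the ANOVA but
when its p-value exceeds 0.05 (configurable) the pipeline proceeds
without any stage correction, recording the decision in the log.

## Tree-aware statistics

**Blomberg's K** uses the Brownian shared-path covariance `C`: with
the phylogenetic GLS mean, K is the ratio of observed to
BM-expected `MSE0/MSE`, normalized so a star tree gives exactly 1.
Significance permutes trait values across tips (999 by default,
one-tailed for K at least as large as observed, add-one corrected).

**Ancestral states** under BM are joint-Gaussian conditional
expectations of node states given the tips, with the root at its
GLS/ML estimate — implemented as a cached linear operator, vectorized
over trait columns (and over simulation replicates, which is what
keeps the convergence null affordable). Estimates are convex
combinations of tip values and therefore lie within the global tip
range; they need *not* lie within the range of each node's own
descendants, because information flows from the rest of the tree too.

**Stayton's C1-C4.** For each unordered pair of focal tips: `Dtip` is
the phenotypic distance between the tips; `Dmax` the maximum distance
between any two reconstructed states (tips included) along the pair's
two lineages back to their MRCA. C1 = 1 - Dtip/Dmax; C2 = Dmax - Dtip;
C3 divides C2 by the total phenotypic change along the two lineages;
C4 by the total change over every edge in the MRCA's clade. Measures
are averaged over pairs; pairs with `Dmax = 0` are undefined and
excluded with a log note. Significance simulates `nsim` BM datasets on
the tree with the per-dimension ML rate and reports the proportion of
simulated values at least as large as observed (add-one corrected).
Simulation — not tip permutation — is used as the null because the
measures depend on reconstructed histories, and permuting tips breaks
the reconstruction rather than the convergence hypothesis. Focal sets
default to family or guild memberships; the measures run on the first
one or two PCs (two by default, matching the plotted morphospaces;
PC1-only mode is exposed). Topology uncertainty repeats the
computation across alternative trees (same seed per tree) and
summarizes per-measure distributions; by default only the values are
recollected there, not per-tree p-values.

**Disparity through time** interpolates trait values linearly along
branches, gradual-change style: at each time-bin midpoint, every
branch spanning that time contributes its interpolated value, and
disparity is the population variance of the contributions (summed over
trait dimensions). Node values come from the BM reconstruction unless
pinned. Bins default to 10 equal-width intervals from the root to the
present; geological-stage edges can be supplied instead. Bins with
fewer than two spanning branches report zero.

## The decoupling battery

Euclidean dissimilarity matrices are computed on the full larval
(Procrustes coordinates) and adult (log-shape ratio) matrices. The
Mantel statistic is the Spearman correlation (average ranks) of the
upper triangles; the null simultaneously permutes rows and columns of
the second matrix; the p-value is one-tailed (9999 permutations
default). The half-sample disparity correlation draws `floor(n/2)`
species without replacement per iteration — the same subset indexing
both matrices, because the Spearman correlation across iterations
needs paired draws — computes both Procrustes variances, and
correlates the 1000 paired values; it runs globally and per family
(families under 6 species skipped). The paired per-species-pair
dissimilarities are exported as the numeric substrate for density
plots.

A caveat worth knowing: the half-sample correlation converges (in the
number of iterations) to a *data-conditional* value, not to zero; its
across-dataset spread under a fully decoupled truth is roughly 0.13 at
n = 80. Single-dataset disparity correlations near ±0.2 are therefore
weak evidence either way, which is why the tests here check its
distribution over replicates rather than a tight per-dataset bound.

## Synthetic data

The generator produces the study conditions end to end: a dated tree
of 83 species in four monophyletic families (22 Alsodidae, 8
Batrachylidae, 20 Cycloramphidae, 33 Hylodidae) on a fixed backbone
(crown 70 Myr; family crowns 35-48 Myr — an Eocene origin with the
two Atlantic-Forest families slightly older, matching the temporal
texture the disparity profiles operate over); 112 landmark
configurations (1-2 specimens per species, Gosner stages 26-41,
32 landmarks on a tadpole-like template); a 10-measurement + SVL adult
table with 10% of measurement cells missing completely at random; and
100 alternative trees (independently regenerated family subtrees) for
topology uncertainty.

Trait evolution is BM (or OU with exact per-branch transitions — no
Euler discretization — for convergence scenarios). Landmark datasets
displace the template along a fixed orthonormal deformation basis:
seeded Gaussian vectors projected off the similarity-transform
subspace (translations, scaling, infinitesimal rotation), so
deformations are pure shape. Digitization noise is iid Gaussian per
landmark (sd 0.005 in unit-centroid-size units); each specimen then
receives a random rotation/translation/scale nuisance transform. Adult
measurements are log-normal with per-measurement allometric slopes
around isometry (1 ± 0.15 sd) against a log-uniform SVL in 20-80 mm,
plus a trait effect and iid noise.

Larval-adult coupling: adult traits are `rho` times an isometric
linear image of the larval BM traits plus `sqrt(1 - rho^2)` times a
stage-specific component that is iid across species (scaled to the BM
tip-variance magnitude). The stage-specific part is deliberately
exchangeable rather than tree-structured: the Mantel permutation test
assumes species exchangeability under the null, and *any*
tree-structured component — even one evolved on an independent tree —
inflates its one-tailed rejection rate severalfold. The exchangeable
design makes `rho = 0` exactly the null the test is calibrated for,
while `rho = 1` with zero noise reproduces the larval geometry
isometrically (Mantel r = 1, disparity correlation = 1). The default
`rho = 0.3` encodes the low-coupling regime the battery is meant to
detect. Because the nuisance transform randomizes specimen scale, the
synthetic larval data carry *no* built-in allometry; the larval
shape-on-size regression in the demo pipeline is a true null, whereas
the adult table carries real allometric structure.

What passing tests on these data do **not** show: robustness to
landmark digitization error structure (correlated along outlines),
non-random missingness, intraspecific variation beyond iid noise,
fossil calibration error, or correlated trait dimensions — none of
which the generator emulates.

## Reproducibility and problem sizes

Every stochastic routine takes an integer seed; the pipeline splits
one root seed into fixed per-stage sub-seeds (SeedSequence on
`[seed, stage_index]`), so a stage rerun alone reproduces its
full-pipeline values, and a rerun of the whole pipeline is
bit-identical apart from wall-clock timings in the manifest. The test
suite validates the battery at desk scale: 500-replicate calibrations
for K and the ANOVA type-I error, 50-seed power curves for the
convergence test at 200 null simulations each, 1000 null pairs for the
Mantel size, and a full 83-species pipeline run at 999 permutations /
200 convergence simulations — sizes chosen to keep Monte-Carlo error
comfortably inside the asserted bounds.

## Known limitations

- GPA has no sliding semilandmarks, 3D support, or tangent projection.
- ASR reports point estimates only (no uncertainty intervals).
- The convergence null fits a single BM rate per dimension; rate
  heterogeneity across clades would require a richer null.
- The Mantel test is not phylogenetically corrected (by design — it
  mirrors the standard battery), so tree-structured residuals in both
  stages inflate it; interpret against the calibration above.
- Imputation assumes an approximately low-rank measurement table and
  missingness unrelated to the missing values.
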