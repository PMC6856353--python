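# Methods

## Twin Cholesky models

The core estimator (`CholeskyTwinModel`) fits univariate and bivariate
ACE/AE models to MZ/DZ twin-pair data by full-information maximum
likelihood.  Component covariances are parameterized as `L L'` with `L`
lower triangular, which keeps A, C and E positive semidefinite by
construction; free and fixed entries of each path matrix are specified as
boolean masks, so constrained specifications (e.g. a shared-environment
loading on the brain variable only, with the C cross path and behavioral C
loading fixed at zero) are part of the model specification rather than
special cases.  Means are equated across twin order and zygosity — one mean
per variable — which is what gives the bivariate AE model its 20 degrees of
freedom against the two-group saturated model.

**Likelihood.**  Families are grouped by zygosity and missingness pattern;
each group's count, mean and scatter are sufficient statistics, so one
likelihood evaluation costs O(number of patterns), independent of sample
size.  A non-positive-definite expected covariance at a trial point is
treated as a rejected point (large penalty), never silently repaired.  On
complete data the pattern-based likelihood equals the direct sum of
2p-dimensional multivariate-normal log densities (tested to 1e-8).

**Optimization.**  L-BFGS-B on the free paths and means, parameterized on
the real line with no boundary constraints; because `L L'` is invariant to
column sign flips, diagonal path signs are normalized nonnegative after
fitting.  The first start comes from moment estimates (Falconer-style
combinations of the observed within- and cross-twin covariances,
eigenvalue-clipped to positive semidefinite and Cholesky-factored);
additional starts jitter it (default 5 starts for standalone fits, 1 for
vertex-wise scans, where the moment start plus warm-started reduced models
proved sufficient and the scan covers thousands of fits).  Convergence
tolerance is 1e-8 on the (relative) objective; if every start fails a
`ConvergenceError` is raised — a failed vertex is flagged invalid in maps,
never reported as a zero effect.

**Derived quantities.**  For p = 2, the genetic correlation is the
correlation implied by the A Gram matrix, `(AA')12/√((AA')11(AA')22)` —
equivalently `a11·a21/√(a11²(a21²+a22²))` — and `rE` analogously from E;
both are undefined (NaN) when a trait has zero corresponding variance.
Bivariate heritability is the genetic contribution to the phenotypic
correlation, `(AA')12/√(S11 S22)` with `S = AA'+CC'+EE'`, i.e. the product
of the standardized 11 and 21 paths; the A, C and E contributions sum to
the implied phenotypic correlation by construction.

**Nested tests and fit indices.**  The chi-square difference test uses
`χ² = 2(llₓ − llᵣ)` clipped at zero with df equal to the free-parameter
difference.  A covariance cross path is an interior parameter, so the naive
chi-square(1) reference is appropriate there; variance-component tests
(e.g. dropping all of C) sit on the boundary and the naive reference is
conservative.  Model df counts two groups of 2p means and 2p(2p+1)/2
covariances minus free parameters.  RMSEA uses n = number of families with
no multi-group adjustment; the baseline (independence) model frees
per-group means and variances with zero covariances, for which the FIML MLE
is available column-wise in closed form.  Published RMSEA/TLI/CFI values
for comparable models depend on unstated sample-size and multi-group
conventions, so exact reproduction of any particular printed triple is not
claimed; the formulas and conventions here are stated so results are
reproducible within this package.

## Phenotype preparation

Scale scores are prorated totals: the mean of answered items times the item
count, valid only when at least 80% of items were answered (configurable);
reverse-coded items are mapped to `max + min − response` before averaging.
Scores are square-root transformed (they are nonnegative counts of
symptom-frequency ratings with right skew), and every variable entering a
twin model is residualized on covariates (sex, mean cortical thickness) by
OLS with an intercept, pooled across all individuals.  Residualization
rejects mutually collinear covariates but treats a constant covariate as
plain demeaning.  Partial correlations are Pearson correlations of the two
residual vectors.

## Vertex-wise mapping

At each vertex the bivariate model has the vertex thickness first and the
behavioral score second, with C free on the vertex only.  The genetic map
stores the signed bivariate heritability and the p-value of the chi-square
difference test on the genetic cross path (a21 = 0); the environmental map
stores the analogous E quantities.  Reduced models warm-start from the full
fit with the tested path zeroed.  Constant-thickness vertices and optimizer
failures are flagged invalid and excluded from clustering.

**Cluster extent.**  Significant vertices (p < α, default 0.05) are split
by association sign *before* connectivity, so each cluster is monotone in
direction, then partitioned into connected components on the mesh edge
graph.  Extent is the component's geodesic diameter — the maximum pairwise
shortest-path distance along edges with Euclidean edge weights — with a
total-surface-area mode (mm², one third of incident triangle areas per
vertex) as a configurable alternative.  The default threshold is 20 mm,
twice a typical 10 mm surface smoothing kernel; edge-graph geodesics
approximate exact polyhedral geodesics well at that scale and are orders of
magnitude faster.  No multiplicity correction beyond cluster extent is
applied; the per-vertex α stays at 0.05.

**Conjunction.**  The overlay of two traits' maps is the vertex-level
intersection of their surviving-cluster unions, re-partitioned into
connected components; components where the traits' signs disagree are kept
but flagged discordant.  No second extent filter is applied to overlays
(small genuine overlaps of two already-corrected maps are themselves
informative); a minimum-vertex option exists for stricter use.

**Split-half replication.**  Families are randomly partitioned into halves
so twin pairs stay together — balanced by default (sizes differ by at most
one), with a Bernoulli per-family mode that allows unequal halves.  Each
half is analyzed at a conjunction α of 0.05 and 20 mm extent; a full-sample
cluster is "replicated" only if it shares at least one vertex, with the
same sign, with a surviving cluster in both halves.  Overlap is
set-intersection, not a proportion, because the criterion is spatial
coincidence rather than size agreement.

## Expression clustering

Gene × region matrices are row z-scored (profile shape, not level) and
clustered by k-means with 10 restarts per candidate k (default k = 1..8).
The cluster count is chosen at the elbow of the WSS curve, operationalized
as the k furthest below the chord joining the curve's endpoints (the knee
of maximum curvature).  Raw second differences were tried first but are
ambiguous between k = 2 and the true k whenever the 1→2 drop is large,
which it always is for well-separated planted profiles; the chord rule
recovers planted k = 2..4 essentially always at moderate separation.
Because the WSS of structureless data also declines smoothly in k, an
elbow is only declared when its chord depth exceeds 20% of the total sum of
squares (structureless matrices measured ≤ ~11%, structured ≥ ~53%);
otherwise one cluster is returned.  Gene filtering removes an explicit
exclusion list (e.g. MHC-region genes, suspect under long-range LD) and
unavailable genes before clustering.

## Synthetic data

The generators are the package's study conditions, not test scaffolding.
Latent additive-genetic factors are standard normal with cross-twin
correlation 1.0 (MZ) / 0.5 (DZ), shared environment is identical within
family, non-shared environment independent; phenotypes are assembled
through explicit Cholesky paths, so the empirical MZ cross-twin covariance
converges to `AA'+CC'` and DZ to `0.5AA'+CC'` (tested element-wise within
3 SE at n = 10,000).  Singletons arise by deleting one co-twin completely
at random, matching the missingness assumption under which FIML is
unbiased — recovery tests are therefore unconfounded by the missingness
mechanism.  Cohort-size defaults (120 MZ + 115 DZ complete pairs,
singleton fraction 0.13) mirror a typical young-adult twin imaging sample;
behavioral generating paths default to rG = 0.40, rE = 0.04 with
heritability 0.45 for both traits, the reported correlations of the
depression–CU model combined with typical twin heritabilities for those
scales (with unit trait variances the standardized paths equal the raw
paths, so those correlations are pinned by construction).

Surface fixtures are subdivided icosahedra (radius 50 mm, roughly cortical
scale) or regular planar grids; planted clusters are geodesic balls, so a
radius-20 mm patch has a 40 mm extent and comfortably passes the 20 mm
filter.  Planted cross paths load the vertex on the *behavior's* genetic
factor, so vertex–behavior covariance is purely genetic and the
environmental map is null by construction.  The generators do not emulate
cortical folding geometry or spatially autocorrelated noise; passing
recovery tests therefore demonstrate correctness of the estimator and the
cluster logic under the model's own assumptions, not robustness to the
spatial noise structure of real MRI data.

## Problem sizes and numerical defaults

Calibration and recovery checks run at: 5,000 + 5,000 pairs for parameter
recovery (standardized path bias < 0.02); 1,000 null cohorts of 200 pairs
for type-I error of the cross-path test; a 2,562-vertex icosphere with
2,000 pairs for planted-cluster recovery (Jaccard > 0.5, COG within 2 mm);
a 642-vertex sphere with 500 pairs for null-map calibration (~5% of
vertices at p < 0.05).  These sizes give binomial/simulation error small
enough for the stated tolerances while keeping the full suite comfortably
runnable on a laptop CPU.

Known limitations: no dominance (ADE) or sex-limitation models, no
ordinal/threshold liability models, no volumetric (VBM) analysis, no
smoothing (inputs are assumed pre-smoothed), and no registration to a
standard space — cluster coordinates are reported in the mesh's native mm
space.
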