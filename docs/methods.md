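# Methods

This note documents the statistical machinery implemented in `ontotraj`,
the choices made where several defensible constructions exist, and what
the synthetic-data generator does and does not emulate.

## Shape and size

Linear measurements (mm) become **log-shape ratios**: per specimen, size is
the natural-log geometric mean of all measurements (both linear tables
combined when a specimen appears in both; a specimen present in only one
table falls back to the geometric mean of its available traits, with a
warning), and each shape variable is `ln(trait) − ln(size)`. By
construction the exponentiated shape variables of a specimen multiply to
one when size comes from the same trait set. Natural log is used wherever
a log transform appears; the tests are invariant to the base, but reported
attribute values need one fixed convention.

Landmark data go through **generalized Procrustes analysis**: centering,
scaling to unit centroid size, and iterative rotation (SVD, proper
rotations only) to the updated mean, convergence when the mean shape moves
less than 1e-8. The final superimposition is rotated so the mean lies on
its principal axes with a fixed 180° convention (largest third-moment
coordinate positive); this makes the result invariant to the input's
orientation and to specimen order. Aligned coordinates are used directly
(no tangent-space projection), as the field's standard toolchain does by
default. **Semilandmarks** slide along tangents estimated from their
neighbor triples (central difference); the tangent displacements minimize
the thin-plate-spline bending energy relative to the current mean (closed
form via the bending-energy matrix of the mean), followed by re-GPA, for
up to 5 outer iterations or until the energy decrease falls below 1e-8.
The **symmetric component** of shape averages each configuration with its
reflected, pair-relabeled, optimally re-aligned copy and re-superimposes
the block. The **sexual-dimorphism filter** runs a distance-based
residual-randomization ANOVA of shape on sex within each species sampled
for both sexes and removes females where p < α (collections of this kind
are male-biased).

## Residual randomization (RRPP)

All shape~size linear-model inference uses distance-based statistics
(sums of squares of the full residual matrix) with null distributions from
permuting reduced-model residuals: `Y* = fitted_reduced + permuted
residuals_reduced`, recomputing the statistic each time. Permutation
p-values everywhere include the observed statistic in the null (add-one
rule), so p ∈ (0, 1]; 10,000 permutations by default (tests and analysis
drivers scale this down where noted). F statistics use sequential
(type I) sums of squares.

Per species, the **isometry test** contrasts `shape ~ size` against the
intercept-only model. The **homogeneity-of-slopes test (HOST)** contrasts
`shape ~ size + species + size:species` against `shape ~ size + species`
(cell-means coding) and reads the interaction F against the residual-
randomized null. The **unique-allometry model** is an ordinary least
squares fit per species; a species' trajectory has direction = unit slope
vector, endpoints = shapes predicted at that species' own smallest and
largest observed size, and length = the distance between those endpoints.

**Pairwise comparisons** of trajectory angle (arccos of the dot product of
unit slope vectors, degrees, full q-dimensional vectors) and length
difference draw their nulls from residual randomization of the common-
slope reduced model; because every pair's statistic is recomputed from the
same randomization, those p-values are left unadjusted. The **intercept
test** (common-slope model per pair, Euclidean distance between intercept
vectors, null from permuting specimen species labels) and the
**peramorphosis test** (distance between phenotypes predicted at each
species' own maximum size, same label-permutation null) are
Benjamini–Hochberg corrected across the pairs tested. "Common slope" for
gating is unadjusted angle p ≥ α.

## Heterochrony (Tfh tests)

Ontogenetic scaling (one shared trajectory in size–shape space, differing
by extension/truncation) and size–shape dissociation (a shared trajectory
in shape space occupied at different sizes) are both **null hypotheses**,
so their p-values are deliberately not corrected for multiple testing.

The statistic must respond to relabeling specimens for the taxonomic-
identity permutation null to be meaningful; a pooled-regression residual
SS does not (it ignores the labels). The implemented statistics are
therefore symmetric **cross-prediction** sums of squares:

* **Tfh1**: fit `shape ~ size` within each species; sum the squared
  residuals of each species' specimens around the *other* species'
  fitted line. On one shared trajectory this sits at the noise floor;
  the null redistributes labels over intact (shape, size) tuples, which
  makes the test exactly calibrated under exchangeability.
* **Tfh2** (only where Tfh1 rejects): the same construction with squared
  *perpendicular* distances from each specimen's shape to the other
  species' regression line in shape space (the size coordinate is
  discarded; the infinite line by default, the fitted segment behind a
  `clamp` flag). A zero slope makes the line degenerate and is an error.

The pooled-regression residual SS is computed and reported alongside
(it is the quantity checked against a normal-equations oracle in the
tests). 10,000 permutations for Tfh1 and 500 for Tfh2 by default.

Each species pair is classified twice, independently: along the decision
path (angle significant → slope shift; else intercept significant →
parallel trajectories; else adult-shape difference significant →
peramorphosis/paedomorphosis; else conserved) and along the Tfh family
(Tfh1 not rejected → ontogenetic scaling; else Tfh2 not rejected →
size–shape dissociation; else neither).

## Juveniles versus adults

Per-species stage phenotypes are the shapes predicted by the unique-
allometry regressions at the species' smallest and largest observed size.

**D test** (run only on clades whose HOST rejects): D = (summed pairwise
Euclidean distances among juvenile phenotypes) − (same among adults);
positive D is ontogenetic convergence, negative divergence. The null
randomizes morphology with respect to size by drawing two random
specimens per species as stage representatives; p is one-sided following
the sign of D. The sum (not a mean-squared disparity) is used, matching
the vector-trajectory literature this follows.

**Phylogenetic signal** is the multivariate generalization of Blomberg's
K: K = (E/PE)/E_BM with E the summed squared deviations of tips from the
GLS phylogenetic mean, PE the phylogenetically corrected counterpart
(C⁻¹-weighted), and E_BM = (tr C − N/Σ(C⁻¹))/(N−1); traits contribute by
summed cross-products, and the univariate case reduces to classical K.
Significance by tip permutation. The stage contrast ΔK = K_adult −
K_juvenile uses the same two-random-specimens null as D; p is the
proportion of permuted ΔK ≥ observed.

**Phylogenetic MANOVA** (simulation-based, Garland-style): covariance PCA
of the species-level response, retaining the smallest leading set of
components with ≥ 95% cumulative variance; sequential F statistics for
size, habitat, and their interaction; the null distribution of each F
comes from multivariate Brownian-motion simulation on the tree (rate
matrix estimated by ML from the PC scores; predictors held fixed).
Species that shift habitat between stages form their own composite
category in trajectory-attribute analyses. Habitat levels represented by
a single species make the interaction term unstable; the result is
flagged, not suppressed.

**Phylomorphospace** node coordinates are maximum-likelihood Brownian
ancestral estimates, computed by GLS from the node-to-tip covariance; the
root estimate equals the phylogenetic mean.

## Evolutionary models

Eight models are fitted to trajectory length and to the first principal
component (covariance PCA) of the slope vectors. All are Gaussian over
tips; σ² and mean parameters are profiled out analytically, leaving a 1-D
(or low-dimensional) search: BM (closed form); OU with a fixed root and
z₀ = θ, so α → 0 recovers the BM likelihood exactly on an ultrametric
tree (a stationary-root variant is available behind a flag); EB with rate
∝ e^{rt}, r ≤ 0; BMS with one σ² per regime of a branch painting
(non-censored: per-regime shared path times); OUM with one optimum per
regime (regime weights are the α-discounted occupancy of the root-to-tip
path, root mass assigned to the basal regime).

The interaction models require an ultrametric tree and decompose it into
inter-branching epochs. **MC** (matching competition): lineage deviations
are attracted to the mean of their co-occurring lineages at rate |S|
(S ≤ 0); within an epoch the covariance obeys dV/dt = AV + VAᵀ + σ²I with
A = S(I − M), M the sympatric-averaging matrix, integrated exactly via
matrix exponentials with Gauss–Legendre quadrature for the inhomogeneous
term; at each branching event the covariance is expanded by duplicating
the splitting lineage. The epoch integrator was verified against a
brute-force Euler–Maruyama simulation of the SDE. **DDl/DD2**: the
diffusion rate is σ₀² + b·n(t) or σ₀²·e^{b·n(t)} with n(t) the count of
co-occurring lineages; the covariance is a shared-path integral with
piecewise-constant rates per epoch. Sympatry enters as a static extant
matrix (symmetric, unit diagonal), mapped onto interior lineages through
their extant descendants; the default is full sympatry. S = 0 and b = 0
reduce all three to BM (verified to ~1e-11 in log-likelihood).

Model ranking uses AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) and Akaike
weights. AICc is undefined (NaN) when n ≤ k + 1; such fits cannot enter a
comparison.

*Known limitation*: under full sympatry the MC among-tip covariance is
nearly compound-symmetric, and a single-optimum OU tracks it closely; on
data simulated under strong MC at 30–40 tips, OU typically attains the
higher maximized likelihood, so AICc rarely prefers MC. The two models
are near-unidentifiable in this regime; informative sympatry structure is
what separates them.

## Branch-specific rates

Phylogenetic ridge regression writes each tip value as root state plus
the sum of (rate × branch length) along its root-to-tip path. The rate
vector is L2-penalized (root unpenalized, minimum-norm solve so λ = 0
remains well defined); λ is chosen by closed-form leave-one-out
cross-validation on tip predictions over a 40-point log grid spanning
nine decades around the design scale, with an error raised if the CV
curve is still strictly decreasing at the upper edge. Ancestral states
are partial path sums. With a covariate (here: trajectory lengths, so
rates are not inflated for species with large ontogenetic change), log
absolute rates are regressed on the branch-level covariate (mean of
parent/child ancestral estimates from the covariate's own ridge
reconstruction) and the residuals are the adjusted rates.

The **shift search** screens every clade with ≥ 6 tips: statistic = mean
clade rate − mean background rate on the screening scale (absolute rates,
or the covariate-adjusted log absolute rates when a covariate was used —
the log transform without adjustment is reserved for visualization, where
near-zero rates otherwise dominate the scale); the percentile of the
observed statistic against rates shuffled across branches (1,000 draws)
gives p, with p > 0.975 flagged higher and p < 0.025 lower.

**Robustness** re-runs rates + shift search on perturbed trees: per
iteration 25% of tips are removed, 25% of internal-node ages are jittered
uniformly within their parent/child brackets, and 25% of tips are
regrafted — only within their smallest enclosing clade whose support
exceeds 0.95, and never inside a constrained subclade, so well-supported
nodes keep their monophyly (with every node constrained, only removals
and age changes alter the tree). A shift is recovered when the rerun
flags a clade with the same verdict whose tips overlap the surviving
original clade at Jaccard ≥ 0.5; the recovery proportion over (default)
100 iterations is reported.

## Synthetic data

The generator emulates museum ontogenetic series and the species-level
processes the comparative tests assume: a pure-birth tree rescaled to
unit height (optionally with uniform node supports, for the robustness
machinery); species slope and intercept vectors evolving under BM
(default) or OU, projected to the zero-sum subspace so the emitted
"measurements" (`exp(size + shape)`) behave exactly like log-shape-ratio
data; habitat use evolving under a symmetric-rates Markov process whose
realized history is painted onto the branches; an exact, requested
fraction of species assigned a juvenile habitat different from the adult
one (arboreal juveniles by default); per-specimen sizes uniform over a
species-specific log-size range with the extremes pinned to the range
ends; isotropic Gaussian shape noise; and optional landmark
configurations produced by thin-plate-spline warps of a bilaterally
symmetric 17-landmark template (3 midline, 4 fixed pairs, 3 sliding
semilandmark pairs) under random rotation, translation and scale.

Defaults: 30 species, 20–40 specimens per species, 6 shape variables,
slope BM rate 0.01 and intercept BM rate 0.04 per unit tree height
(tip-level SDs of roughly 0.1 and 0.2 in log-shape units), noise SD 0.05,
minimum size ln-uniform over [2.5, 4.5] (≈ 12–90 mm) with an ontogenetic
span of 0.8–1.5 log units (≈ 2.2–4.5-fold growth), habitat leave-rate 1
per tree height over six categories, 20% stage-shifters. These are
plausible magnitudes for squamate ontogenetic series: a few dozen
species, series that span hatchling to large adult, allometric
coefficients of order 0.1, and measurement/individual noise well below
the ontogenetic signal.

What the generator does *not* emulate: correlated (non-isotropic) shape
noise, ontogenetically varying noise, non-uniform size sampling,
empirical trait covariance of any particular clade, measurement error in
the tree, or fossil/non-ultrametric tips. Passing calibration and
recovery tests on these fixtures therefore demonstrates correctness of
the machinery under its stated assumptions, not robustness to the messier
structure of real collections.

Constructed fixtures back the classification and detection tests: five
two-species scenarios (truncation; shape overlap with shifted sizes;
rotated slope; orthogonal parallel offset; identical trajectories) whose
expected categories are known by construction, and a divergence fixture
whose juvenile phenotypes sit in a ball of radius r and adults in radius
r(1 + strength).

## Numerical conventions

* Random streams: every routine draws from a child generator derived
  from the master seed and a routine-specific name (CRC32 spawn key), so
  results do not depend on execution order.
* Rank-revealing QR for all design bases; saturated models (zero residual
  SS) give infinite F where the term explains variance, zero otherwise.
* Trees: strictly positive branch lengths and unique tips enforced;
  ultrametricity within 1e-6 × height required by epoch-based methods;
  painting segments must sum to branch lengths within 1e-6.
* Newick round trips preserve lengths to repr precision (≪ 1e-12) and
  internal-node supports (labels parsing as numbers in [0, 1]).
* 1-D likelihood searches: 8-point grid then bounded Brent polish;
  α and rate parameters searched on log scale with bounds scaled by tree
  height; BMS relative rates by L-BFGS-B from three starts.
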