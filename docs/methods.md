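# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `pcmkit`, and what the synthetic-data generator does and
does not emulate.

## Tree representation and covariances

Trees are rooted with branch lengths in time units; node times run forward
from the root (root age 0).  Posterior samples need not be perfectly
ultrametric: every formula uses root-relative node times, so slight
non-ultrametricity (within a relative tolerance of 1e−6 for the
`is_ultrametric` classification) is tolerated rather than corrected.
Because DTT and the EB/OU transforms work in relative time (divide by tree
height), absolute units cancel everywhere except in reported rate and pull
parameters, which are per unit branch-length time.

Three covariances are built from the MRCA-age matrix:

* **BM**: `V_ij = s_ij`, the root-to-MRCA shared time; diagonal =
  root-to-tip distance.
* **OU (fixed-root)**: `V_ij = (1/2α)(1 − e^(−2α s_ij)) e^(−α d_ij)`.  The
  fixed-root (non-stationary) form is the standard choice for ultrametric
  comparative data; it treats the root state as a parameter rather than a
  draw from the stationary distribution.  A single scalar α is shared
  across traits, matching the convention of reporting one pull strength per
  dataset.  As α → 0 the form tends to BM (verified to 1e−5 relative at
  α = 1e−8).
* **EB/ACDC**: rate `e^(r t)`, implemented as the branch transform
  `(e^(r t2) − e^(r t1))/r` (series limit `t2 − t1` used below |r| = 1e−12).
  The BM covariance of the transformed tree is the EB covariance.

EB rate conventions: internally the rate-decay exponent is `r` (per unit
time, r ≤ 0).  Correlation structures for univariate GLS are often pinned
through a present/root rate *ratio* `g`; we map `g = e^(r·height)`, i.e.
`r = ln(g)/height`, so g = 0.5 means the rate halves over the tree.  The
univariate PGLS/EB structure fixes g = 0.5 by default (so the structure is
a genuine early burst and adds no free parameter); multivariate GLS
profiles r by ML and counts it as a parameter.

## Trait preparation

All variables are analysed on a natural-log scale.  Percentage-scaled
variables are divided by 100 before the log; variables that can be zero or
negative get a documented additive offset (e.g. +100 for coldest-month
minimum temperature, +1 for driest-month precipitation).  Shape is defined
as `ln(x/SVL)` — simultaneously the log transform and the size ratio —
with `ln(SVL)` retained as body size; this single convention resolves the
order ambiguity between "log-transform" and "take ratios".  Missing values
in one morphological variable are imputed by OLS on a complete predictor
(body size), flagged in metadata.  Specimens are averaged to species
*after* the log transforms, so species means behave like geometric means
of raw measurements.  PCA reduction uses the correlation matrix (centre +
unit-variance scale): environmental blocks mix units and scales, making
covariance PCA indefensible; axes are retained up to a cumulative-variance
threshold (default 99%) and signs are fixed so each axis's
largest-magnitude loading is positive.

## Disparity through time

Disparity defaults to the average pairwise **squared** Euclidean distance
(computed as `2/(m−1) · Σ_i |x_i − x̄|²`), with plain Euclidean distance as
a named option — the two conventions coexist in the literature, so both
are explicit.  The curve is evaluated at every distinct internal-node age
(root first) plus the present: at age *t*, every lineage crossing *t*
(taken just after any divergence at *t*) contributes its subclade's
disparity relative to the whole clade, singleton lineages contributing 0;
the root point is the whole clade (value 1) and the present is 0.  This
follows the written definition — *all* subclades present at a time, with
the average taken at that node's own time — rather than any particular
legacy implementation (some average only non-singleton clades selected at
the previous time slice).  An independent time-slice oracle in the test
suite pins the contract.

The null is constant-rate multivariate BM with the rate matrix (full
matrix, i.e. correlated BM, not independent per-trait rates) and root mean
estimated by ML from the data on the same tree; nulls are re-estimated on
each posterior tree, matching per-tree iteration semantics.  MDI is the
trapezoid area of (observed − null mean) over relative time; positive MDI
= more late/within-subclade disparity than BM.  Per-tree curves are
interpolated onto a common 100-point relative-time grid; the posterior
summary is the across-tree mean curve and the 2.5/97.5 percentile interval
of MDI.  For plots the displayed band pools the per-tree null envelopes.

## Model fitting and comparison

For the species-by-trait matrix X, each model induces
`vec(X) ~ N(vec(1μ'), R ⊗ V(θ))`.  Given θ, the GLS mean
`μ̂ = (1'V⁻¹1)⁻¹1'V⁻¹X` and ML rate matrix `R̂ = (X−1μ̂)'V⁻¹(X−1μ̂)/n` are
closed-form, so fitting is a bounded deterministic 1-D search over θ
(α ∈ [1e−6, 50/height] for OU, r ∈ [−10/height, 0] for EB; five interval
restarts, golden/parabolic refinement).  The bounds keep the covariance
numerically sane: α·height = 50 is already far beyond any resolvable pull,
and r·height = −10 compresses late history to numerical zero.  Estimation
is ML, not REML: the likelihood target is what AICc compares.  Cholesky
factorisation gets a three-step jitter retry (starting at 1e−10·tr(V)/n)
before failing.

Parameter count: `k = p + p(p+1)/2 + (1 for OU/EB)` — root means, free
rate-matrix entries, structural parameter.  AICc uses **n = number of
species** (consistent with the univariate collapse arithmetic: equal
likelihoods at n = 26 give a 3-vs-2-parameter AICc gap of 2.569 and
weights 0.644/0.178/0.178).  When n ≤ k + 1 the AICc is undefined (NaN)
and model comparison refuses rather than silently substituting AIC.
Posterior summaries report per-model weight mean with 2.5/97.5 percentile
interval, AICc mean ± sd, α and r mean ± sd, and the consensus best model
(most tree wins); per-tree records are retained so every summary cell is
recomputable.  Measurement error is available as an optional per-trait
nugget only through the residual machinery, not enabled by default: the
study conditions it would mimic are unknowable without raw specimen
variances.

## Regression and group tests

All GLS works in whitened space (premultiplying by the inverse Cholesky
factor of V(θ)).  Univariate PGLS reports parametric t tests (and F = t²
for comparability with multivariate statistics) with df = n − q.
Multivariate GLS shrinks the whitened-residual ML covariance `S` linearly
toward a unit-variance target: `Σ̂(λ) = (1−λ)S + λ(tr S/p)I`, with λ
maximising the leave-one-out cross-validated Gaussian log-likelihood of
whitened residuals.  The LOO criterion is computed exactly in O(np) per λ
via an eigenbasis + rank-one-downdate identity (verified against the
direct per-row computation in tests); λ is chosen on a 41-point grid with
golden-section refinement, and θ (when free) by a nested bounded search
with relative tolerance 1e−4 — well below any downstream sensitivity.

The MANOVA statistic is Wilks Λ = det(E_full)/det(E_reduced) from whitened
residual cross-products; the null distribution permutes rows of the
whitened *reduced-model* residuals and adds back the reduced fit
(Freedman–Lane), with `p = (1 + #{Λ* ≤ Λ_obs})/(n_perm + 1)`.  The
univariate group test is the GLS sequential F with parametric p.  The
significance threshold behind "proportion of trees supporting" defaults to
0.05 and is configurable.

Correlation-structure choice for a response–predictor comparison is made
once, by per-tree AIC majority vote across the posterior (ties break
toward the simpler structure, BM > OU > EB), then held fixed for the
per-tree fits — a per-comparison decision, not a per-tree one.  Predictor
axes are tested in separate regressions by default (axis-wise statistics),
with a joint-design mode available.  Univariate p-values are parametric,
multivariate p-values permutation-based; outputs label which, so the
univariate-vs-multivariate sensitivity of conclusions can be examined on
synthetic data.

## Synthetic studies: what they emulate and what they do not

`generate_study` emulates the *structure* of a small-radiation dataset: 26
species, an ultrametric birth–death base tree rescaled to height 5 (a
clade a few million years old), a pseudo-posterior (default 100 trees;
tests use fewer for speed), a phenotype block (body size ~55 mm plus five
limb/body measures emitted on the raw mm scale so the preparation path
exercises and exactly inverts them), environment blocks shaped like PC
axes (3 vegetation + 2 temperature + 2 precipitation + elevation), a
clade-based north/south bipartition at the root, optional missing-value
injection, and an optional planted linear dependence of all shape columns
on the first vegetation axis.  Default rates: shape/size 0.02 per unit
time on the log scale (≈14% trait sd over the tree height, a realistic
morphometric spread), environment axes 0.5.  Planted effect sizes:
null 0.0; moderate 0.05; strong 0.10, calibrated once to give ≈0.9 power
for the single-tree multivariate test at these noise levels.

The pseudo-posterior jitters age *increments* (waiting times) with a
lognormal of the requested CV — increments stay positive, so no node ever
collides with its parent and covariance conditioning is preserved — then
rescales so realized tree heights have exactly the requested CV (default
0.1); topology is perturbed by nearest-neighbour interchanges applied
per internal edge with probability 0.1.  The dendropy birth–death
simulator stops exactly at the n-th speciation; pendant edges are extended
by a sampled exponential waiting time so no two tips are perfectly
correlated.

What the generator does **not** emulate: genuine Bayesian posteriors
(whose trees are draws from a correlated posterior, not perturbations of
one truth), within-species sampling variance, measurement error,
spatially structured environments, or non-Gaussian trait distributions.
Consequently, passing tests demonstrate the estimators' correctness and
calibration under their stated models — they do not certify behaviour
under model violations real data may show.  One such effect is visible
even inside the generator: because data are simulated on the base tree,
per-tree tests on *perturbed* trees are mildly anticonservative (type-I
≈ 0.15 at jitter CV 0.1 for the multivariate permutation test), which is
the phylogenetic-uncertainty problem these posterior-iterated summaries
exist to expose.  Calibration tests therefore simulate each null dataset
on the tree it is analysed with — the hypothesis the tests themselves
state — and the mismatch effect is reported here rather than hidden.

## Problem sizes and determinism

Default analysis sizes used by the test suite and the reproduction script:
26 species, 20-tree posteriors, 199 permutations, 200 DTT null simulations,
200 replicates for calibration/recovery studies, 64 tips for OU pull
recovery.  These sizes give stable Monte-Carlo estimates (binomial 99%
bounds, 3-standard-error checks) while keeping a full run within minutes
on one CPU; the pipeline accepts larger values (e.g. 1000 trees, 999
permutations) unchanged.  Every source of randomness derives from a single
root seed; per-tree and per-simulation streams are derived deterministically
(seed + index), so posterior iteration is reproducible regardless of
evaluation order, and pipeline stages derive their streams from a stable
CRC of the stage tag.

## Known limitations

* Single-regime models only: no multi-peak OU, rate shifts, or
  reversible-jump averaging.
* The OU structure assumes a scalar α shared across traits.
* Permutation tests assume exchangeability of whitened residuals; under a
  misspecified tree this is only approximate (see above).
* DTT offers a BM null only (no OU/EB nulls, node-height tests, or
  rank-envelope corrections).
* Trees are consumed, never inferred; divergence-time estimation and
  species delimitation are out of scope.
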