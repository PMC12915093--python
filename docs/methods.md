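# Methods

This note documents the models implemented in `idopnet`, the choices made
where the design was genuinely open, the study conditions the synthetic-data
generators define, and the known limits of what the method can identify.
Nothing here reports an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Indices: a quasi-dynamic axis for static data

The pipeline's ordering variable is never time. For one graft segment the
**compartment index** E_i = Σ_j y_ji (total expression of sample i)
summarizes the segment's transcriptional state; the **ecosystem index** sums
the two segments of the same plant; the per-gene **niche index**
N_i = y_{j,scion,i} + y_{j,rootstock,i} drives that gene's two-compartment
crosstalk model. Samples are reordered by the ascending index, with ties
broken by original sample position (a stable sort), so the axis is
deterministic. Samples with identical index values are kept as distinct
observations; they are collapsed to unique knots only inside ODE
integration, which requires a strictly increasing grid, and mapped back to
samples for every likelihood evaluation.

Assumption made explicit: expression is treated as a *function of the
index*. Two samples with equal indices are expected to have equal
expression up to noise. Where that is false (e.g., hysteresis in real
development), the model sees extra residual variance.

## 2. Allometric power fits

Each gene's relation to its index is y_j(E) = α_j E^{β_j} (α_j > 0, β_j
the scaling exponent). Fitting is raw-scale least squares: log–log ordinary
least squares on strictly positive pairs initializes β; a bounded profiled
1-D search refines it (α has a closed form given β); the initializer is
kept whenever its raw-scale residual is lower, which makes noiseless data
exact. Zeros in y are excluded from the log–log step but included in the
refinement; a log-scale fit (multiplicative error model) is available via
`log_scale=True`. Raw-scale fitting was chosen so the residuals match the
additive-noise model of the clustering and network likelihoods.

## 3. Legendre curve algebra

Independent and dependent kernels are finite Legendre series P_0..P_r in a
linearly normalized variable t ∈ [−1, 1]. The default order is r = 4 for
all kernels, configurable per stage: with ~24 samples per grid, five
coefficients per kernel is the most flexibility the data support.
Differentiation and integration are exact linear maps on coefficients (with
the chain-rule factor 2/(hi−lo)), which justifies estimating the system in
integral space: an integrated kernel has the same coefficients as the
kernel itself. Evaluation outside a curve's fitted domain raises by
default; during ODE fitting the state is clamped to the domain (kernels are
only meaningful over observed expression ranges, and clamping keeps
integration defined while the optimizer explores).

## 4. SAD(1) residual covariance

Residuals along the ordered grid follow the nonstationary innovation-driven
first-order antedependence recursion e_1 = ε_1, e_i = φ e_{i−1} + ε_i with
iid N(0, ν²) innovations. This variant has closed forms used throughout:
covariance ν² φ^{|t−s|}(1−φ^{2 min(s,t)})/(1−φ²), determinant ν^{2n}
(independent of φ), and a bidiagonal whitening likelihood. Because the
determinant does not involve φ, the profile maximum-likelihood estimates
are closed-form: φ̂ is the lag-one regression of residuals and ν̂² the mean
squared innovation — this is what makes profiling the covariance inside
every optimizer evaluation affordable.

The two-compartment form couples the scion and rootstock residuals of one
combination. Two variants exist:

- `sad.block_cov`: cross-covariance ρ_c σ^S_i σ^R_i at matching grid
  positions in the *original* space, assembled densely and validated
  positive definite (rejected, not projected, when it is not). This is the
  form used by the crosstalk joint likelihood.
- `clustering.InnovCov`: the same SAD blocks with ρ applied to the
  *innovations*. This form has a closed-form inverse and determinant
  (per-position 2×2 blocks after whitening), so the clustering E-step and
  the covariance M-step are exact and fast. The dense original-space form
  required a derivative-free optimization over the 2n×2n assembly at every
  EM iteration and made the module-count study an order of magnitude
  slower; the innovation form is the package's covariance model for
  clustering, a deliberate design choice.

## 5. Functional clustering

Genes are clustered by a K-component Gaussian mixture over their
trajectories; each module's mean per variate is a power curve and the
residual covariance is shared across modules (SAD per variate, the
innovation-coupled pair form within a combination, independence across
combinations). The octa-variate version concatenates all four combinations
× two segments.

EM details, in the generalized-EM (GEM) form:

- E-step: exact posteriors; the observed log-likelihood is computed here
  and is asserted nondecreasing (tolerance 1e−9 relative).
- π update: exact.
- Mean update: per module and variate, a grid-refined profiled search for
  (α, β) against the posterior-weighted mean curve; the update is accepted
  only if it does not lower the expected complete-data objective under the
  current covariance. Rejection is rare but guarantees monotonicity.
- Covariance update: closed-form (lag-one φ, innovation-moment ν², ρ),
  Q-checked the same way.
- Stopping: log-likelihood gain below max(1e−6, 1e−8·|loglik|); the
  relative component matters because at |loglik| ~ 1e5 an absolute 1e−6
  threshold merely burns the iteration cap.
- Initialization: k-means on log1p trajectories, deterministic given the
  seed. Empty components (posterior mass < 1e−8) trigger a re-seeded
  restart, at most five.

Model selection minimizes BIC = −2 loglik + p log m over K, with p counting
mixing proportions, per-module-per-variate (α, β), and covariance
parameters, and m (genes) as the sample count; each K gets three seeded
restarts keeping the best likelihood. Hard assignment is by maximum
posterior with ties to the lower module index. Recursive subdivision
re-runs selection inside every leaf larger than `max_leaf` (default 100, a
Dunbar-scale network size) down to depth 4, labeling children
M# → SM#_# → SM#_#_#. A homogeneous oversized leaf whose best model is
K = 1 is kept oversize with a warning rather than force-split.

## 6. Regulator selection (group Lasso)

Integrating the ODE system turns it into an additive regression: the
observed y_j over the ordered grid equals an unpenalized self block plus
one group per candidate regulator. Each group is the *running integral* of
the Legendre design evaluated along the regulator's smoothed curve,
X̃[i,k] = ∫ P_k(t(ŷ_{j′}(s))) ds — pointwise designs would let the self
block span the identity map of the gene's own trajectory and make the
regression self-explaining. The self block is the integrated own-kernel
family plus an intercept carrying y(E_1). The weight function is the
quadratic bump Z_i = (E_i−E_1)(E_n−E_i)/((E_n−E_1)/2)², zero at both
boundary samples.

The solver is proximal block-coordinate descent (majorize–minimize per
group; the objective is nonincreasing across sweeps and groups are exactly
zero at and above λ_max), jitted over a 50-value log-spaced path from
λ_max down to 1e−3 λ_max with warm starts; λ = 0 falls through to the exact
weighted least-squares solution. The penalty is chosen by BIC
(n log(wRSS/n) + df log n, df = all active coefficients) or extended BIC
(+2γ log C(m−1, k), γ = 0.5 default); (near-)saturated path entries with
df ≥ n−1 are excluded from the criterion, and ties go to the sparser
model. Curve smoothing for the designs uses a Legendre fit in the index
(order 4–6), which preserves the non-monotone features that make
regulators distinguishable; power-equation smoothing is available but
makes every curve monotone and the candidates nearly collinear.

## 7. Network fitting and testing

Fitting is gene-by-gene conditional maximum likelihood: regulator inputs
are frozen at their smoothed trajectories, so the dependent drive is a
known function of E, precomputable as a design-matrix product, and only a
single state is integrated per gene (fixed-grid fourth-order Runge–Kutta
over the unique knots; midpoint drives are the average of adjacent knot
drives so that observed and permuted fits are treated identically).
Component integrals accumulate with the same RK4 stage weights as the
state, so y(E_1) + ∫independent + ∫dependent = trajectory holds to machine
precision — the conservation identity behind the decomposition plots.
Kernel coefficients are optimized by Nelder–Mead (cap 2000 evaluations)
with SAD(1) covariance profiled in closed form per evaluation; the
independent kernel initializes from the finite-difference slope of the data
against its own state and the dependent kernels from the group-Lasso
coefficients (finite-differenced integral fits). The null
(independent-only) solution is always evaluated inside the full parameter
space, so the likelihood ratio LR = 2(l₁ − l₀) is never negative.

Interaction testing uses a conditional LR computed by one fixed protocol:
the dependent kernels are seeded in closed form by regressing the
independent-only residual on the running integral of the regulator designs,
then polished by a short Nelder–Mead from the null solution. The null
distribution applies the identical protocol to *rotated* (cyclically
shifted, optionally reflected) regulator trajectories. Rotations rather
than full reshuffles matter: a reshuffled regulator curve is rough, while
the observed one is smooth, so under full permutation any smooth misfit of
the independent-only fit aligns better with the observed design than with
every null design — measured type-I error was 0.30 at nominal 0.05.  With
the rotation null and symmetric optimization budgets the measured type-I
error is 0.025.  The cost is power: a rotated drive explains a broad trend
reversal nearly as well as the correctly phased one, so the test is
conservative (see §10).  Edge significance is the gene-level call applied
to the gene's incoming edges.
Edge weight is the mean of the dependent-component derivative over the
grid (a single signed scalar per edge; full curves are retained on the
edge objects).

Graph analytics run on the undirected unweighted skeleton: mean shortest
path over connected pairs, average local clustering, vertex connectivity
and diameter of the largest component. Hubness is eigenvector centrality of
the |weight| adjacency by power iteration with a positive diagonal shift
(the shift preserves the Perron vector and prevents the oscillation that
plain iteration exhibits on bipartite components), normalized to max 1 per
component. Information-flow tracing enumerates simple directed paths up to
six hops with multiplicative sign algebra, ordered by the product of edge
magnitudes.

## 8. Crosstalk typing

For each gene the rootstock (l = 1) and scion (l = 2) rows form the coupled
pair dy_1/dN = f_1(y_1) + f_{1←2}(y_2), dy_2/dN = f_2(y_2) + f_{2←1}(y_1)
over the gene's niche index. A joint Nelder–Mead fit of all four kernels
against the block scion/rootstock likelihood provides the decomposition
curves (conservation holds per compartment).

Classification does **not** reuse the joint fit's decomposition, because
that split is not identifiable in-sample (see §10). Each direction is
assessed conditionally:

- The target compartment's autonomous null dy/dN = f(y) is fit once; the
  residual deviation from it is everything the counterpart could have
  contributed.
- Significance: the R² of that deviation on the counterpart's Legendre
  design, compared with the same regression on fully permuted counterparts
  ((1−α) quantile, default 200 permutations). A deviation whose RMS is
  below 0.5% of the data RMS is never called (that is the optimizer's own
  error floor on clean data, far below any meaningful displacement).
  This test detects engineered effects reliably on clean data but is
  anticonservative under observation noise, for the same smooth-vs-rough
  asymmetry as above; the calibrated variants evaluated (rotation nulls,
  generalized-least-squares whitening, noise-scaled floors) each
  suppressed genuine detections as strongly as false ones and were
  rejected.  §10 discusses what this means for the typing accuracy the
  validation studies report.
- Sign and size: the deviation averaged with weights |d̂| from its aligned
  projection, concentrating the average on the counterpart's active
  window.

The two signs map onto the nine interaction types through the 3×3 table
(scion→rootstock effect × rootstock→scion effect); a compartment exerting a
positive effect is the dove, a negative one the hawk. Swapping the two
input rows swaps the two directions exactly, by construction.

## 9. Synthetic-data generators: the study conditions

The generators define the conditions under which the validation studies
run. They emulate the reciprocal-grafting design (four combinations × two
segments, 8 index points × 3 replicates = 24 samples per segment,
log-uniform index grids) with known ground truth.

**Modules** (`sim_modules`): gene j in module k follows
α_{kv} E^{β_{kv}} × (1 + gene-level jitter) + SAD(1)-correlated noise, the
model-matched form. Defaults: K = 4 modules with β evenly spaced on
[0.3, 1.5] (±0.05 per-variate wobble); module curve levels drawn on a
*common scale* (20–60 at the mid-grid index, α derived from it) — a shared
residual covariance cannot serve modules whose magnitudes differ by orders
of magnitude, and with independent α draws module-count selection provably
over- or under-splits; additive SAD noise with innovation SD 10% of the
median signal, φ = 0.3, scion/rootstock ρ = 0.3; per-gene scale jitter
0.5%. The jitter ceiling matters: the mixture has no per-gene scale term,
so persistent scale heterogeneity above roughly 2% of signal is resolved by
BIC as additional modules — which is also why real data produce dozens of
modules and why recursive subdivision exists. Per-point multiplicative
noise is available as a misspecification knob (default off).

**Networks** (`sim_network`): 20 genes on a 100-point grid, at most 3
parents per gene, 5% multiplicative observation noise. Self-kernels are
switch-like (a small baseline drift plus a localized activation bump the
state crosses at a gene-specific threshold), producing slow–fast–slow
trajectories whose break locations differ per gene; edge kernels are
centered on the source's autonomously visited state range (two-pass
construction), so the drive is zero-mean over the path — only the
state-dependent part of a drive is attributable to a specific source, a
constant drive being a ramp any kernel reproduces.

**Crosstalk pairs** (`crosstalk_pair`): mean-reverting self-kernels with a
small positive pedestal (states relax upward), plus one signed Gaussian
bump per nonzero direction in the counterpart's state. A negative bump
forces a transient dip, a positive one an overshoot past equilibrium and
return — either way the affected compartment's trend reverses, which no
autonomous model reproduces. Draws are validated (positive states,
strictly increasing niche index, a material ≥5% trend reversal per active
direction) and redrawn until valid; the symmetric cells (mutualism,
antagonism) satisfy all three constraints only rarely and may need hundreds
of redraws.

What the generators do *not* emulate: library-size and batch effects,
count noise at low expression, hysteresis (expression that is not a
function of the index), regulation that changes sign across the index
range, and unmodeled confounders shared across genes. Passing tests
therefore demonstrate internal consistency and recovery under the model's
own assumptions, not performance on real RNA-seq.

## 10. Identifiability: what the method can and cannot recover

Three structural facts shaped this implementation and bound what any
fitting procedure can do with this model class; the validation studies
reflect them.

1. **Autonomous absorption.** A scalar autonomous ODE y′ = f(y) can
   reproduce any monotone trajectory exactly (f = slope ∘ y⁻¹) and any
   smooth one approximately at order r. Dependent drives are therefore
   detectable only through features the self-kernel cannot express —
   chiefly trend reversals, where the trajectory revisits a state with a
   different derivative. The network and crosstalk generators build such
   features in deliberately; on featureless monotone data the likelihood
   ratio is honestly near zero.

2. **Attribution requires localized, source-specific features.** Groups of
   smooth candidate designs over ~10²-point grids span nearly identical
   function spaces (in the study diagnostics, random wrong regulator pairs
   explained a smooth target as well as the true pair). The selector itself
   is sound — on incoherent designs its 2-of-29 support recovery is high —
   but end-to-end edge recovery on trajectory data is limited by design
   coherence, and the end-to-end study reports what the full loop actually
   achieves under the stated conditions.

3. **Drive/self-kernel sign trade-off.** A transient pulse in a trajectory
   is explained equally well by a one-signed drive plus a restoring
   self-kernel or by a biphasic drive with a different self-kernel; the
   likelihood cannot separate them from a single pair of length-24
   trajectories. Crosstalk *detection* (is there a directional effect?) is
   reliable; the *sign* of the effect is only partially identifiable, and
   the estimator implemented (deviation weighted by its counterpart-aligned
   projection) was the best-performing of several evaluated variants. The
   nine-cell exact-typing study makes this limit visible rather than hiding
   it.

## 11. Numerical choices

- RK4 on the unique-knot grid; ~16× endpoint-error reduction on step
  halving is asserted as the order check.
- Nelder–Mead for all kernel optimizations (the model family is
  low-dimensional and non-smooth at clamping boundaries); caps: 2000
  evaluations for observed fits, 150–300 for permutation refits,
  warm-started so observed and permuted statistics get comparable
  optimization effort.
- Degenerate inputs: constant index grids, constant regulator curves, and
  non-positive-definite covariance assemblies raise typed errors; a gene
  whose optimizer stalls is retained with its best-found parameters and
  flagged.
- All randomness flows from integer-seeded `SeedSequence` hierarchies
  (per-gene streams in the generators), so every artifact is reproducible
  bit-for-bit; the pipeline manifest records content hashes to make this
  checkable.
- Study sizes in `scripts/acceptance.py` (e.g., 6 clustering seeds, 3
  network runs) are the package's desk-scale defaults; the test suite runs
  the same studies at the larger replicate counts stated in each test.
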