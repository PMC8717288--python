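# Methods

This note records what the estimators in `stemspat` compute, the
assumptions and defaults behind them, what the synthetic forests emulate,
and the numerical choices a user auditing results should know about. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Observation model

A stem map is a marked point pattern observed in a union of long, narrow
rectangles — parallel inventory transects. The emulated design is eight
east–west transects, 50 m wide, 6250 m long, 450 m apart (centre to
centre), tiled by 25 m × 50 m subplots: 2000 subplots, 250 ha. Stems carry
a species code, a regeneration guild (SLP, LLP, NPLD, STS), and dbh ≥ 10
cm (the survey threshold; smaller stems are rejected at read time with a
count). Stem files use coordinates local to their transect; all distances
are computed in a global frame where transect k is offset by k·450 m, so
cross-transect separations (400 m gaps and up) are meaningful for the
correlograms.

"Standardized" diameters are dbh divided by the species mean — a ratio,
not a z-score. This removes interspecific growth-rate and maximum-size
scale before pooling species into guild-level correlograms, while leaving
each species' relative dispersion intact; the intertype statistic already
standardizes by species-level σ where that matters.

## Pair correlation and Ripley's K

The estimators pool pairs over transects but use only within-transect
pairs; the gaps between transects are unobserved, and at the default
r ≤ 1000 m no cross-transect pair could contribute to K anyway. The
translation edge correction weights a pair with displacement (dx, dy) by
|W|/ν(dx, dy), where ν is the set covariance of the whole window (the sum
of per-rectangle terms (a−|dx|)⁺(b−|dy|)⁺). This is exact for rectangles
and ratio-unbiased for K(r) = πr² under CSR, which the test suite verifies
by simulation.

g(r) uses an Epanechnikov kernel with divisor r. The default half-width is
Stoyan's rule h = 0.15/√λ̂ (λ̂ in stems/m²; about 8 m at 3 stems/ha over
250 ha). The r grid defaults to 10–1000 m in 10 m steps; r = 0 is excluded
(division by r), and a warning is raised when r exceeds half the narrowest
window dimension — on 50-m-wide transects, g at r ≫ 50 m is effectively a
one-dimensional statistic with growing variance, which is reported rather
than hidden.

**Envelopes.** `n_sim` (default 100) CSR patterns are simulated with the
observed stem count in the same window; the envelope is the pointwise
(α/2, 1−α/2) band of the simulated g values. Quantiles use the Weibull
plotting position so that a draw from the null falls outside the band with
probability ≈ α even at n_sim = 100 (the default interpolation of sample
quantiles would give ≈ 7% at a nominal 5%). The bandwidth is frozen at the
observed pattern's value across observed and simulated estimates.

**Classification.** The verdict is read from the smallest scanned distance
outward, matching how aggregation is reported in transect studies
("aggregated up to X m"): *aggregated* (resp. *regular*) when g leaves the
upper (lower) bound on a contiguous run starting at the first grid point,
with the extent equal to the upper end of that run; otherwise *random*,
unless an interior contiguous significant run longer than
`min_interior_run` occurs, which is flagged *mixed*. Because the kernel
smears a single chance fluctuation over ≈ 2h of the r axis, adjacent grid
values are positively correlated and a sub-bandwidth run is one effective
test, not several; the default therefore requires the interior run to span
more than 2h (three grid points at default settings) before flagging.
A pointwise envelope scanned at many distances will still be left
somewhere by chance in a few percent of CSR patterns — the classification
is calibrated, not exact.

## Moran correlograms

Distance classes are half-open (c_lo, c_hi], by default (0,100] … 
(3900,4000] m; pairs at distance exactly 0 (self pairs, co-located stems)
belong to no class. I(c) follows the classical distance-class form with
the global mark mean and variance; classes without pairs are reported
missing (NaN), and classes with fewer than 30 pairs are flagged
low-support because the variance of I explodes there. The permutation
envelope permutes marks over the fixed locations (999 draws by default,
pointwise Weibull quantiles); the exact randomization mean −1/(N−1) is
verified in the tests.

The intertype statistic I12 sums over ordered cross pairs, standardizing
each species by its own mean and divisor-N standard deviation. The
divisor-N choice makes the self-comparison collapse exactly to I(c) —
a regression-tested identity. Its null envelope permutes each species'
marks independently.

The Mantel test correlates the upper triangles of two square matrices and
permutes rows/columns of the second jointly; p is two-sided on |r| with
the add-one rule. The diameter variant correlates z_i z_j (standardized
marks) against ln d_ij, so cohort structure appears as negative r;
coincident stems get d = 0.5 m before the log, with a warning.

## Canonical correspondence analysis

The response is the chi-square standardized table
Q̄ = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}; total inertia is ‖Q̄‖², the CA total.
Predictors are weighted-centred and row-weighted (X_w = D_r^{1/2}(X − x̄_w));
the constrained part is the orthogonal projection of Q̄ onto col(X_w),
computed through an SVD basis so collinear predictors reduce to their span
(with a rank warning) rather than failing. Constrained + residual inertia
equals the total identically (orthogonal projection); the tests assert it
to 1e−8 and check a 4×3 toy table against an independent dense-eigen
oracle and against scikit-bio's implementation.

Categorical predictors expand to indicator contrasts against a reference
level ("flat" for topography when present), so a 4-level factor carries
df = 3. Sites with zero total abundance are dropped with a logged count —
a CCA row weight of zero is undefined — as are all-zero species columns.

**Permutation tests.** The model test permutes predictor rows against the
fixed community. Marginal term tests remove the term, permute the
residuals of the reduced model across sites, and refit the full model
(residual-permutation scheme); p = (1 + exceedances)/(1 + n_perm). Axis
tests compare each constrained eigenvalue against its distribution under
whole-row permutation of X — a simultaneous test, not one conditioned on
earlier axes.

**Model search.** Backward elimination under
AIC = n·ln(residual inertia/n) + 2(1 + rank of constraints). There is no
canonical AIC for CCA; this deviance-style analog is adopted and the full
elimination trace is returned so the search can be audited. Like ordinary
AIC it retains a pure-noise term at a nontrivial per-term rate (~20–30%),
so selected models should be read together with the marginal permutation
tests. Variance decomposition reports each term's marginal chi-square
(full minus term-deleted constrained inertia) as a share of constrained
inertia, both raw — shares need not sum to 100% with correlated
predictors — and normalized.

## Synthetic forests

The generator is a pure function of (config, seed) and exists so that
every downstream statistic can be checked against known truth. Default
guild densities follow the inventory that motivated the design (SLP 3.33,
LLP 3.19, NPLD 18.73, reference STS 4.77 trees/ha; eight species). Three
templates encode the competing explanations for light-demander abundance:

* **h1 (disturbance cohorts)** — SLP species are Thomas cluster processes
  (parents 0.08/ha, cluster σ = 40 m, offspring count set by the target
  density) whose stems take the growth-curve dbh of their patch's age
  (uniform 20–120 yr) plus Gaussian noise (σ = 5 cm), floored at 10 cm.
  The growth curve is a saturating von Bertalanffy form with a 150 cm
  asymptote and rate 0.02/yr — no field growth model is implied; only the
  within-patch similarity of diameters matters for the tests. Patch sizes
  and ages are free parameters of the scenario, not estimates of any real
  site's history.
* **h2 (random placement)** — every species homogeneous Poisson with
  independent (shifted-lognormal, ≥ 10 cm) diameters.
* **h3 (environmental filtering)** — the reference shade-tolerant species
  is an inhomogeneous Poisson process thinned by exp(−d_water/τ), τ =
  120 m, normalized to its target mean density; τ was chosen by the
  closed form of the thinning integral so that ≥ 70% of its stems fall in
  the lowest distance-to-water quartile of the landscape.

The environment is a subplot grid with altitude = base + gentle
along-transect gradient + smooth interpolated noise − Gaussian valleys at
the configured river lines (rivers are vertical lines crossing all
transects; adequate for distance-to-water gradients without real
hydrology). Slope is |∂altitude/∂x| in percent; topography is a
deterministic function of altitude quantiles and slope (crest above the
80% quantile, shallow below 20%, slope above 2%, else flat — strict
comparisons so a perfectly flat field is all "flat"). Valleys at rivers
induce the positive altitude–distance-to-water correlation real
floodplains show.

What the generator does **not** emulate: demographic dynamics (mortality,
recruitment, competitive thinning — so the gradual erosion of aggregation
over succession is out of scope), dispersal kernels, soil, measurement
error in coordinates, and irregular transect geometry. Passing recovery
tests therefore show the estimators detect the encoded structures at
realistic densities and survey geometry; they do not show how those
structures decay in real forests.

## Problem sizes and determinism

Every stochastic stage takes a seed; the pipeline derives per-stage,
per-unit sub-seeds by hashing (master seed, stage, unit), so adding a unit
never shifts another unit's randomness and a config + seed pair reproduces
a report byte for byte. The validation runners use: 200 simulations for
the Poisson/Thomas closed-form calibrations (single 2000 m × 50 m
transect), 200 replicates × 100-simulation envelopes for the exceedance
calibration (1000 m transect, 100 stems), 10 000 permutations for the
randomization mean, and 50 independent forests per scenario for the
recovery rates, with the pair-correlation scan limited to 10–250 m
(several cluster diameters) and correlogram classes to 1000 m. These sizes
keep the whole validation run within a coffee break on a single core while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The pair-correlation estimate on 50-m transects at r ≫ 50 m mixes 1-D
  and 2-D geometry; the variance grows and the warning should be taken
  seriously when interpreting extents of several hundred metres.
* Pointwise envelopes do not control the family-wise error over the r
  grid; the classification rule compensates at the origin but "mixed"
  flags should be read as exploratory.
* The marginal-share decomposition of correlated predictors is not a
  partition; only the orthogonal case sums to the constrained total.
* The axis permutation test is simultaneous, not sequential-conditional;
  its p-values for later axes are conservative when the first axis is
  strong.
* No inhomogeneous or anisotropic pair correlation, no Geary's c, no
  partial (conditioned) CCA.
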