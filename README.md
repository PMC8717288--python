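# stemspat

Spatial pattern analysis of rainforest stem maps: pair-correlation
functions with Monte-Carlo null envelopes, Moran's I correlograms of stem
diameter (including an intertype, between-species variant), Mantel
permutation tests, and canonical correspondence analysis (CCA) with
permutation pseudo-F inference — plus a synthetic transect-forest
generator so every statistic can be validated against a known
data-generating process.

The package is aimed at forest and plant ecologists asking how the trees
of a species (or of a light-response guild: short-lived pioneers SLP,
long-lived pioneers LLP, non-pioneer light demanders NPLD, shade-tolerant
STS) are arranged in space, whether spatially close stems have similar
diameters (the signature of disturbance cohorts), and how much of the
community's composition is explained by environmental covariates.

## The statistics

**Pair correlation function.** For a point pattern of intensity λ in a
window W, g(r) = K′(r)/(2πr) compares the density of pairs at separation r
with the expectation under complete spatial randomness (CSR): g(r) > 1
means aggregation, g(r) < 1 regularity. `stemspat` estimates g with an
Epanechnikov kernel (Stoyan bandwidth h = 0.15/√λ̂ by default) and the
translation edge correction, which is exact for the rectangular windows of
transect surveys; only within-transect pairs contribute. Significance
comes from pointwise envelopes of `n_sim` CSR simulations with the
observed stem count; a pattern is *aggregated up to X m* when the observed
g leaves the upper envelope on a contiguous run of distances starting at
the smallest scanned r.

**Moran's I correlogram.** For diameters m_i observed at the stem
locations, within distance class c = (c_lo, c_hi]:

    I(c) = N / (Σ w_ij) · Σ_{i≠j} w_ij (m_i − m̄)(m_j − m̄) / Σ_i (m_i − m̄)²

with w_ij = 1 iff d_ij ∈ c. Its randomization expectation is −1/(N−1);
significance uses random mark permutations over the fixed locations, plus
a Mantel test between the pairwise mark-product matrix z_i z_j and
ln(d_ij). The intertype variant correlates two species' diameters, each
standardized by its own mean and (divisor-N) standard deviation:

    I12(c) = Σ_i Σ_j w_ij (m1_i − m̄1)(m2_j − m̄2) / (σ1 σ2 Σ w_ij)

and collapses exactly to I(c) when species 2 is a copy of species 1.

**CCA.** The chi-square standardized site × species table is projected
onto the span of the row-weighted environmental predictors; constrained +
residual inertia equals the correspondence-analysis total by construction.
Model, axis and marginal-term significance use permutation pseudo-F tests
(999 permutations by default); model search is backward elimination under
a deviance-style AIC analog with the full trace exposed.

## Worked example

```python
import numpy as np
from stemspat import (scenario_template, gen_community, standardize_dbh_by_species,
                      CSREnvelope, MoranCorrelogram, DistanceBins)

cfg = scenario_template("h1")            # disturbance-cohort forest, 250 ha
stems, subplots, truth = gen_community(cfg, seed=1)
std = standardize_dbh_by_species(stems)
slp = std[std["guild"] == "SLP"]         # pooled short-lived pioneers
pts = cfg.window.to_global(slp)

env = CSREnvelope(cfg.window, r_grid=np.arange(10., 260., 10.),
                  n_sim=100, random_state=1).fit(pts)
print(len(slp), env.classification_, env.extent_m_)

cor = MoranCorrelogram(bins=DistanceBins(np.arange(0., 1100., 100.)),
                       n_perm=199, mantel=False, random_state=1).fit(
    pts, slp["mark"].to_numpy())
print(round(cor.i_[0], 3), cor.significant_[0])
```

prints

```
772 aggregated 150.0
0.664 True
```

— the 772 pioneer stems are classified aggregated up to 150 m (the
clusters have a 40 m dispersal scale, so the pair excess fades by a few
cluster diameters), and the first distance class (0–100 m] shows strong
positive diameter autocorrelation (I ≈ 0.66, outside the permutation
envelope): spatially close pioneers belong to the same cohort.
On an "h2" forest (random placement, independent diameters) the same code
reports `random` and a first-class I inside the envelope.

The full study workflow (species filter at n ≥ 50, per-species and
per-guild envelopes, correlograms, SLP intertype tests, four-way CCA with
and without the reference species) runs with `stemspat run --config
run.yaml --out report/` or `stemspat.run_study(RunConfig(...))`.

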