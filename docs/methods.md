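# Methods

## Model and assumptions

`ecoevodiv` implements a continuous-time quantitative-genetics community
model.  Each of S species is a Gaussian cloud in an L-dimensional trait
space, characterized by density N_i, mean μ_i, and genetic covariance G_i;
the phenotypic covariance is P_i = G_i + E_i with E_i a fixed, non-heritable
environmental covariance.  The mean changes along the selection gradient
scaled by G P⁻¹ (the multivariate breeder's equation in continuous time), and
G itself evolves under selection on (co)variances, scaled by G P⁻¹ · P⁻¹ G.
Key inherited assumptions: trait distributions stay Gaussian (random mating;
no speciation possible), populations are effectively infinite (no drift,
no demographic noise), and genetic variance has no upper bound (infinite
standing variation).  When G → 0 evolution stops entirely — G = 0 is an
absorbing, neutrally stable manifold — which is the mechanism behind frozen
narrow-niche communities.

Growth rates derive from competition for a resource continuum.  With
Gaussian resource-utilization curves of covariance W = (ω²/4)I and the
reciprocal supply normalization, three closed identities hold, each verified
by quadrature in the test suite:

* the resource-intake integral is identically 1 (hard-coded after one-time
  numerical verification; no resource grid is represented anywhere);
* the phenotype-phenotype competition kernel is exp(−|z−z′|²/ω²);
* species-species competition coefficients and all fitness moments are
  Gaussian expectations with closed forms (quartic mortality moments use
  sixth-order Isserlis identities, cross-checked against the ∂m₀/∂μ and
  ∂m₀/∂P gradient identities).

Production code uses only the closed forms; quadrature in two or more
dimensions would be far too slow for the experiment grid, so the numerical
oracles (dense Simpson grids, adaptive quadrature, Monte Carlo) live in the
test suite and anchor correctness there.

## Parameters

| parameter | meaning | default / levels | units |
|---|---|---|---|
| L | trait dimensions | 1, 2, 3 | — |
| ω | competition width | {0.1, 0.15} (L=1), {0.25, 0.3} (L=2), {0.4, 0.45} (L=3) | trait |
| θ | mortality scale | 1/2 | trait |
| m(z) | mortality shape | (z·z)/θ² or (z·z)²/θ⁴ | rate |
| G_i(0) | initial genetic breadth | U[0.01, 0.05] (low) or U[0.05, 0.1] (high) | trait SD |
| E_i | environmental breadth | U[0.005, 0.008] / [0.015, 0.018] / [0.025, 0.028] | trait SD |
| μ_i(0) | initial means | U[−0.5, 0.5] per dimension | trait |
| N_i(0) | initial densities | 1 | density |

The factor levels for genetic and environmental breadths are interpreted on
the **trait-standard-deviation scale**: initial G eigenvalues and E diagonal
entries are the *squares* of values drawn uniformly from the level ranges.
This is a deliberate reading.  Taken as raw covariance entries instead, the
environmental trait breadth (σ_E ≈ 0.07–0.17) would be comparable to the
competition width ω itself, no amount of variance narrowing could reduce
niche overlap between neighbors, and the model's central results disappear
(the SD–FD correlation comes out *positive* for the full model).  On the SD
scale, σ_E ≪ ω in every cell of the design, the trait-narrowing mechanism
operates, and the package reproduces all qualitative signatures of the
model: variance collapse in packed communities, fitness landscapes pinned at
zero at species means, the negative SD–FD association under the full model,
the positive association under the frozen-covariance null (which also packs
fewer species), functional diversity spanning roughly a decade, and ~6+
species coexisting at ω = 0.15 in one dimension.

## Numerical integration

The flow is stiff across ten decades of time: selection on variances slows
quadratically as G → 0 (dG ∝ G²), so fixed-step explicit integration is
infeasible.  `integrate` uses SciPy's LSODA (adaptive, switches to BDF when
stiff) on the packed state [N, μ, upper-triangle(G)] per species, in
segments between ~50 logarithmically spaced checkpoints (which also bound
trajectory memory over long horizons).  At each checkpoint:

* genetic covariances are projected onto the PSD cone — eigenvalues in
  (−floor, 0) are clamped to 0, where floor = max(100·atol, 1e−12); anything
  more negative raises, since the exact flow preserves PSD and only round-off
  should violate it;
* densities are clamped at 0 (the exact dynamics keep N > 0; round-off near
  extinction can undershoot);
* the derivative max-norm is tested against `equilibrium_tol` (default
  1e−10) for early stopping.

Default tolerances are rtol 1e−6 / atol 1e−9.  Default horizon is 1e10 time
units — long enough for eco-evolutionarily stable equilibria — but the desk-
scale protocol slice and the tests use t_end = 1e6 with early stopping,
which the packing analyses show is ample for the one-dimensional slice
(most runs stop early at the derivative-norm threshold).

Species are never removed from the state: extinction is bookkeeping only
(`extinction_threshold`, default 1e−6, tags `n_extant`), and the q = 2 Hill
diversity automatically discounts vanishing species.  Whether near-extinct
species should instead be pruned is a known ambiguity; keeping them is the
conservative choice and changes q = 2 diversities negligibly.

## Diversity metrics

Hill numbers use the analytic q → 1 limit (exponential Shannon entropy), for
both species diversity and the gridded functional diversity.  Functional
diversity evaluates the community trait density at *cell centers* (not cell
averages) of a 101-bin grid per dimension on [−1, 1], normalizes across
cells, and regularizes the Hill number by 1/C — so FD = 1 means uniform
coverage of the gridded window, and a point mass gives 1/C.  Center
evaluation is a deliberate fidelity choice; refining 101 → 201 bins moves FD
of smooth densities by well under 1% (tested).  Resource depletion reduces,
for this kernel, to [(2π)^L det 2W]^{1/4} · ΣN_i — exactly proportional to
total biomass; it is reported alongside biomass, never substituted for it,
and the proportionality is asserted as a property (a richer resource model
would break it).

## Experiment harness

The full factorial design is 3 (L) × 24 (S₀ ∈ 2..25) × 2 (initial G) × 3 (E)
× 2 (ω) × 2 (mortality) = 1728 cells × 10 replicates.  Seeds derive from a
counter-based scheme (`SeedSequence(master_seed)` spawned per design index ×
replicate), so every run is reproducible from the master seed and row index
alone and batches can run in any order.  All random components (μ, G, E) are
redrawn per replicate; statistical rather than bitwise reproduction of the
original protocol is the goal, since no RNG scheme is canonical.  Each
seeded point runs twice from bit-identical initial conditions — full model
and frozen-covariance null (dG/dt ≡ 0) — and failures are recorded as
unconverged rows without aborting the batch.

Desk-scale defaults: the packaged slice (tests and `scripts/acceptance.py`)
uses L = 1, S₀ ∈ 2..12, both ω, low initial-G, low E, quadratic mortality,
5 replicates, t_end 1e6 — about 220 integrations in a few minutes on one
CPU.  Quadratic mortality and the low covariance levels are where the
variance-evolution effect is strongest (larger E weakens it, since E sets a
floor on trait breadth); the full grid remains available via
`build_design()` / the `experiment` CLI for larger studies.

## Empirical pipeline

Input is individual-level: one row per specimen with species, island,
vegetation zone (arid/humid — ranges never span both, so island × zone pairs
are independent subcommunities), and two shell traits (centroid size, shape
PC1; the PC axes are consumed as given, not computed).  Cleaning drops
configured satellite islands (defaults CH, ED, GA) and species with fewer
than `min_individuals` = 3 specimens — 3 being the minimum for the binormal
ML fit, so the rule reproduces the removal of under-sampled species from
data rather than hard-coding any species name.

Traits are rescaled per axis to [−1, 1] by the pooled min/max of the whole
cleaned dataset: one shared frame for all subcommunities, required for FD
values to be comparable, and the least arbitrary choice available.  Species
densities are binormal ML fits (mean, 1/n covariance) or Gaussian KDEs
(SciPy's Scott plug-in bandwidth by default, exposed as a parameter);
abundance-weighted mixtures give the community trait density and FD on the
shared 101² grid.  Species diversity (Hill q = 2 of sampled relative
abundances) is divided by the subcommunity's host-plant count, a proxy for
the number of available ecological opportunities.  The SD–FD relationship is
summarized by OLS with a two-sided t test on the slope (no multiplicity
correction — it is one illustrative regression).

Because recorded abundances reflect sampling effort rather than true
densities, `abundance_randomization` redraws each subcommunity's species
weights — uniform on the simplex (symmetric Dirichlet(1), concentration
exposed) by default, or multinomially at the observed sampling depth — and
reports the fraction of trials with a negative slope.  Both modes are
provided because the original randomization distribution is not specified.

## Synthetic fixture generator

`generate_fixture` emulates the empirical data's structure: isolated
subcommunities of binormal species clusters with unequal per-species
sampling intensities (±50% around the nominal sample size by default) and
attached host-plant counts.  Species richness rises across subcommunities
(2 up to a configurable maximum); within-species trait SD either shrinks
steeply with richness (σ = 0.4/S², the trait-narrowing regime, yielding a
negative SD–FD relationship by construction) or stays fixed at σ = 0.06
(yielding the naive positive relationship).  Ground-truth parameters are
returned for recovery tests.  What the generator does *not* emulate:
non-Gaussian or skewed trait clouds, measurement error, spatial structure
within subcommunities, phylogenetic relatedness among species, and
covariation between abundance and trait position.  Passing pipeline tests
therefore demonstrate estimator consistency and sign recovery under the
model's own assumptions, not robustness to the messiness of real specimen
tables.

## Known limitations

* The G = 0 manifold is absorbing: once variance collapses numerically,
  means freeze too, so some equilibria are frozen configurations rather than
  isolated stable fixed points; longer horizons shift them only
  logarithmically.
* Multiple equilibria exist; outcomes depend on seeds.  All batch-level
  claims are ensemble (rank-correlation) properties, not per-run claims.
* The resource-depletion measure is degenerate with biomass under this
  kernel (see above).
* Asymmetric, nonlocal, or hierarchical competition kernels, speciation,
  and stochastic population dynamics are out of scope.
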