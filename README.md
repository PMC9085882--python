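# ecoevodiv

Eco-evolutionary community dynamics under Gaussian resource competition, with
species- and functional-diversity metrics, a factorial simulation protocol,
and an individual-level trait-table pipeline for isolated island communities.

## The scientific problem

Does species diversity beget functional diversity?  On ecological timescales
more species usually means more trait space covered.  But when intraspecific
trait variation can *evolve*, species in tightly packed communities are
selected to narrow their trait breadths to avoid competing with neighbors —
and that narrowing can erase, or even reverse, the expected positive
relationship between species diversity (SD) and functional diversity (FD).
`ecoevodiv` implements a quantitative-genetics community model in which this
tension arises, the diversity statistics to measure it, a frozen-covariance
null model that removes it, and an empirical pipeline for individual-level
trait tables from isolated subcommunities (island × vegetation-zone snail
assemblages).

## The model

For each of S species in an L-dimensional trait space, the state is the
population density N_i, the trait mean vector μ_i, and the genetic covariance
matrix G_i; the phenotype distribution is Gaussian with covariance
P_i = G_i + E_i, where E_i is a fixed environmental covariance.  Writing
r(**z**) for the per-capita growth rate of phenotype **z** and
p_i(**z**) = 𝒩(**z**; μ_i, P_i),

    dN_i/dt = N_i ∫ r(z) p_i(z) dz
    dμ_i/dt = G_i P_i⁻¹ ∫ (z − μ_i) r(z) p_i(z) dz
    dG_i/dt = G_i P_i⁻¹ [ ½∫ ((z−μ_i)(z−μ_i)ᵀ − P_i) r(z) p_i(z) dz ] P_i⁻¹ G_i

The growth rate comes from competition for a continuum of resources with
Gaussian utilization curves of covariance **W** = (ω²/4)**I** (ω is the
competition width): the resource-intake term is identically 1, mortality is
m(z) = (z·z)/θ² (or its square), and competition between phenotypes reduces
to the Gaussian kernel exp(−|z−z′|²/ω²).  Every integral above then has a
closed Gaussian form; the test suite verifies each against independent
quadrature and Monte Carlo oracles.

Species diversity is the Hill number of order q of relative abundances
(q = 2, the inverse Simpson index, by default).  Functional diversity is a
regularized Hill number of the community trait probability density
𝒟(z) = Σ f_i p_i(z), evaluated on a grid of C cells (101 bins per dimension
on [−1, 1]): FD = (1/C)(Σ 𝒟̂_c^q)^{1/(1−q)} ∈ (0, 1], equal to 1 for uniform
coverage of the gridded region.

## Worked example

```python
import numpy as np
from ecoevodiv import (IntegratorOptions, integrate, run_null,
                       functional_diversity, hill_number)
from ecoevodiv.experiments import DesignPoint, sample_initial_community

opts = IntegratorOptions(t_end=1e6)
for S0 in (3, 10):
    pt = DesignPoint(L=1, S0=S0, g_level="low", e_level="low",
                     omega_level="high", mortality_shape="quadratic",
                     replicate=1, seed=5)
    com = sample_initial_community(pt, np.random.default_rng(5))
    fin = integrate(com, opts).final
    G = np.mean([sp.G[0, 0] for sp in fin.species if sp.N > 1e-4])
    print(f"S0={S0}: SD={hill_number(fin.frequencies(), 2):.2f} "
          f"FD={functional_diversity(fin):.3f} mean G={G:.2e}")
```

prints

```
S0=3: SD=2.24 FD=0.387 mean G=9.81e-03
S0=10: SD=6.30 FD=0.075 mean G=3.57e-05
```

Seeded with 3 species (ω = 0.15), the community equilibrates with substantial
genetic variance (G ≈ 1e−2) and covers about 39% of the trait axis.  Seeded
with 10, far more species persist (SD ≈ 6.3) but each collapses onto its
environmental variance floor (G ≈ 4e−5), and total trait-space coverage
*drops* to 7.5% — higher species diversity, lower functional diversity.
Re-running the same communities with `run_null` (trait covariances frozen)
restores the familiar positive SD–FD relationship.

There is also a CLI: `ecoevodiv simulate|diversity|experiment|empirical --help`.

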