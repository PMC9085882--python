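"""Independent numerical oracles for the closed-form Gaussian machinery.

Everything here integrates the model's defining integrals numerically —
dense Simpson grids and adaptive quadrature in 1-D, Monte Carlo in higher
dimensions — without using the production closed forms, so agreement is a
genuine two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, simpson

from ecoevodiv.model import Community, ModelParams


def utilization(params: ModelParams, z: float, y: np.ndarray) -> np.ndarray:
    """1-D resource utilization curve u(z, y) from its definition."""
    W = params.omega**2 / 4.0
    det2W = params.omega**2 / 2.0
    norm = (2.0 * np.pi * det2W) ** 0.25
    gauss = np.exp(-((z - y) ** 2) / (2.0 * W)) / np.sqrt(2.0 * np.pi * W)
    return norm * gauss


def resource_supply(params: ModelParams) -> float:
    """Saturation resource concentration R0 (constant over y) in 1-D."""
    det2W = params.omega**2 / 2.0
    return (2.0 * np.pi * det2W) ** -0.25


def intake_integral(params: ModelParams, z: float) -> float:
    """Adaptive quadrature of the resource-intake term: integral u(z,y) R0 dy."""
    val, _ = quad(lambda y: utilization(params, z, y) * resource_supply(params),
                  z - 30 * params.omega, z + 30 * params.omega, limit=200)
    return val


def kernel_quad(params: ModelParams, z: float, zp: float) -> float:
    """Adaptive quadrature of the kernel: integral u(z,y) u(z',y) dy."""
    lo = min(z, zp) - 30 * params.omega
    hi = max(z, zp) + 30 * params.omega
    val, _ = quad(lambda y: utilization(params, z, y) * utilization(params, zp, y),
                  lo, hi, limit=200)
    return val


def _norm_pdf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)


def pairwise_competition_dblquad(
    params: ModelParams, mu_a: float, P_a: float, mu_b: float, P_b: float,
    n: int = 1201,
) -> float:
    """Double Simpson integration of p_a(z) k(z-z') p_b(z') over both traits.

    The inner kernel is evaluated by its definition via a y-grid, so no
    closed form enters anywhere.
    """
    sa = np.sqrt(max(P_a, 1e-12))
    sb = np.sqrt(max(P_b, 1e-12))
    za = np.linspace(mu_a - 8 * sa - 4 * params.omega, mu_a + 8 * sa + 4 * params.omega, n)
    zb = np.linspace(mu_b - 8 * sb - 4 * params.omega, mu_b + 8 * sb + 4 * params.omega, n)
    y = np.linspace(min(za.min(), zb.min()) - 6 * params.omega,
                    max(za.max(), zb.max()) + 6 * params.omega, n)
    ua = utilization(params, za[:, None], y[None, :])  # (n, n)
    ub = utilization(params, zb[:, None], y[None, :])
    # y-integral via trapezoid weights (memory-light matrix product)
    w = np.gradient(y)
    kern = (ua * w) @ ub.T
    pa = _norm_pdf(za, mu_a, max(P_a, 1e-12))
    pb = _norm_pdf(zb, mu_b, max(P_b, 1e-12))
    inner = simpson(kern * pb[None, :], x=zb, axis=1)
    return float(simpson(inner * pa, x=za))


def landscape_grid(params: ModelParams, N, mu, P, z: np.ndarray) -> np.ndarray:
    """Fitness landscape r(z) on a grid, all integrals done numerically.

    The competition term integral k(z-z') p_j(z') dz' uses a dense Simpson
    grid over z' with the kernel computed from exp(-d^2/omega^2) -- itself
    independently validated against the y-quadrature by kernel_quad tests.
    """
    r = 1.0 - (z**2) / params.theta**2
    if params.mortality_shape == "quartic":
        r = 1.0 - (z**2) ** 2 / params.theta**4
    for Nj, muj, Pj in zip(N, mu, P):
        s = np.sqrt(Pj)
        zp = np.linspace(muj - 10 * s, muj + 10 * s, 4001)
        pj = _norm_pdf(zp, muj, Pj)
        kern = np.exp(-((z[:, None] - zp[None, :]) ** 2) / params.omega**2)
        r = r - Nj * simpson(kern * pj[None, :], x=zp, axis=1)
    return r


def moments_simpson(
    params: ModelParams, N, mu, P, i: int, n: int = 6001
) -> tuple[float, float, float]:
    """Simpson-grid fitness moments of species i for a 1-D community.

    Returns the mean fitness, selection differential, and half the variance
    selection integral, matching the closed-form triple.
    """
    span = max(np.sqrt(max(p, 1e-12)) for p in P)
    lo = min(mu) - 12 * span - 8 * params.omega
    hi = max(mu) + 12 * span + 8 * params.omega
    z = np.linspace(lo, hi, n)
    r = landscape_grid(params, N, mu, P, z)
    pi = _norm_pdf(z, mu[i], P[i])
    x = z - mu[i]
    m0 = simpson(r * pi, x=z)
    m1 = simpson(x * r * pi, x=z)
    M2 = 0.5 * simpson((x**2 - P[i]) * r * pi, x=z)
    return float(m0), float(m1), float(M2)


def community_1d_arrays(com: Community):
    """Convenience: (N, mu, P) scalars lists for a 1-D community."""
    N = [sp.N for sp in com.species]
    mu = [float(sp.mu[0]) for sp in com.species]
    P = [float(sp.P[0, 0]) for sp in com.species]
    return N, mu, P


def random_community_1d(
    rng: np.random.Generator, S: int | None = None, mortality: str = "quadratic"
) -> Community:
    """A randomized small 1-D community for oracle sweeps."""
    from ecoevodiv.model import SpeciesState

    S = S or int(rng.integers(1, 5))
    params = ModelParams(
        L=1, omega=float(rng.uniform(0.08, 0.3)), theta=0.5, mortality_shape=mortality
    )
    species = [
        SpeciesState(
            N=float(rng.uniform(0.05, 2.0)),
            mu=[float(rng.uniform(-0.5, 0.5))],
            G=[[float(rng.uniform(0.0, 0.03))]],
            E=[[float(rng.uniform(1e-5, 0.01))]],
        )
        for _ in range(S)
    ]
    return Community(params, species)


def random_community_nd(
    rng: np.random.Generator, L: int, S: int | None = None,
    mortality: str = "quadratic",
) -> Community:
    """A randomized small L-dimensional community for Monte Carlo checks."""
    from ecoevodiv.model import SpeciesState

    S = S or int(rng.integers(1, 4))
    params = ModelParams(
        L=L, omega=float(rng.uniform(0.2, 0.45)), theta=0.5, mortality_shape=mortality
    )
    species = []
    for _ in range(S):
        A = rng.normal(size=(L, L)) * 0.06
        species.append(
            SpeciesState(
                N=float(rng.uniform(0.05, 1.5)),
                mu=rng.uniform(-0.4, 0.4, L),
                G=A @ A.T,
                E=np.diag(rng.uniform(1e-4, 0.01, L)),
            )
        )
    return Community(params, species)
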