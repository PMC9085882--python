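"""Core types and closed-form Gaussian machinery for the eco-evolutionary model.

The model follows ``S`` competing species in an ``L``-dimensional quantitative
trait space.  Each species is described by its population density ``N``, trait
mean vector ``mu`` and genetic covariance matrix ``G``; together with a fixed
environmental covariance ``E`` these determine the (Gaussian) phenotype
distribution ``p_i(z) = N(z; mu_i, P_i)`` with ``P_i = G_i + E_i``.

Phenotypes consume a continuum of resources with a Gaussian utilization curve
of covariance ``W = (omega^2/4) I`` around their trait value, which yields

* an intrinsic per-capita growth ``1 - m(z)`` (the resource-intake integral of
  the underlying consumer-resource model is identically 1 for the chosen
  utilization/supply normalization, so only the mortality ``m`` remains), and
* a Gaussian competition kernel ``a(d) = exp(-|d|^2 / omega^2)`` between
  phenotypes separated by ``d`` in trait space.

Every integral needed by the dynamics (growth-rate averages over phenotype
distributions, selection gradients, selection on (co)variances) is a Gaussian
expectation with a closed form; those closed forms live here.  The test suite
checks them against independent numerical quadrature and Monte Carlo oracles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SpeciesState",
    "Community",
    "mortality",
    "intrinsic_growth",
    "competition_kernel",
    "pairwise_competition",
    "fitness_landscape",
    "fitness_moments",
]

MortalityShape = Literal["quadratic", "quartic"]

#: eigenvalues below this are clamped when inverting covariance matrices
EIG_FLOOR = 1e-12


def _as_vector(x, L: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (L,):
        raise ValueError(f"{name} must be a length-{L} vector, got shape {v.shape}")
    return v


def _as_matrix(x, L: int, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.shape != (L, L):
        raise ValueError(f"{name} must be {L}x{L}, got shape {m.shape}")
    return m


def _check_symmetric(M: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    if not np.allclose(M, M.T, atol=tol, rtol=0.0):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


def _min_eig(M: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(M)[0])


def _psd_check(M: np.ndarray, name: str, tol: float = 1e-9) -> np.ndarray:
    M = _check_symmetric(M, name)
    if _min_eig(M) < -tol:
        raise ValueError(f"{name} must be positive semidefinite")
    return M


@dataclass(frozen=True)
class ModelParams:
    """Global constants of the fitness landscape and competition kernel.

    Parameters
    ----------
    L : int
        Trait-space dimensionality (>= 1).
    omega : float
        Competition width, in trait units.  The competition kernel between two
        phenotypes a trait distance ``|d|`` apart is ``exp(-|d|^2/omega^2)``.
    theta : float
        Mortality scale, in trait units (default 1/2).  Sets the extent of the
        region where intrinsic growth is positive.
    mortality_shape : {"quadratic", "quartic"}
        Shape of the intrinsic mortality function, ``m(z) = (z.z)/theta^2`` or
        ``m(z) = (z.z)^2/theta^4``.
    """

    L: int
    omega: float
    theta: float = 0.5
    mortality_shape: MortalityShape = "quadratic"

    def __post_init__(self) -> None:
        if not (isinstance(self.L, (int, np.integer)) and self.L >= 1):
            raise ValueError(f"L must be an integer >= 1, got {self.L!r}")
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.mortality_shape not in ("quadratic", "quartic"):
            raise ValueError(
                f"mortality_shape must be 'quadratic' or 'quartic', "
                f"got {self.mortality_shape!r}"
            )
        object.__setattr__(self, "L", int(self.L))
        object.__setattr__(self, "omega", float(self.omega))
        object.__setattr__(self, "theta", float(self.theta))

    @property
    def W(self) -> np.ndarray:
        """Utilization covariance, ``(omega^2/4) I``."""
        return (self.omega**2 / 4.0) * np.eye(self.L)

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "omega": self.omega,
            "theta": self.theta,
            "mortality_shape": self.mortality_shape,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            L=d["L"],
            omega=d["omega"],
            theta=d.get("theta", 0.5),
            mortality_shape=d.get("mortality_shape", "quadratic"),
        )


@dataclass
class SpeciesState:
    """One species' dynamical state: density, trait mean, and covariances.

    ``G`` is the genetic (heritable, evolving) covariance, ``E`` the
    environmental (non-heritable, fixed) covariance; the phenotypic covariance
    is ``P = G + E``.  ``E`` may be singular here (point phenotypes are useful
    limits for the pairwise-competition formula), but the dynamics require a
    positive-definite ``P``.
    """

    N: float
    mu: np.ndarray
    G: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        L = self.mu.shape[0]
        if self.mu.ndim != 1:
            raise ValueError("mu must be a vector")
        self.G = _psd_check(_as_matrix(self.G, L, "G"), "G")
        self.E = _psd_check(_as_matrix(self.E, L, "E"), "E")
        self.N = float(self.N)
        if self.N < 0:
            raise ValueError(f"N must be nonnegative, got {self.N}")

    @property
    def L(self) -> int:
        return self.mu.shape[0]

    @property
    def P(self) -> np.ndarray:
        """Total phenotypic covariance, ``G + E``."""
        return self.G + self.E

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "mu": self.mu.tolist(),
            "G": self.G.tolist(),
            "E": self.E.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesState":
        return cls(N=d["N"], mu=d["mu"], G=d["G"], E=d["E"])

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            N=self.N, mu=self.mu.copy(), G=self.G.copy(), E=self.E.copy()
        )


@dataclass
class Community:
    """A set of species sharing one parameterization; the full model state.

    Species identity is positional: species are never reordered or removed,
    so index ``i`` refers to the same lineage along a whole trajectory.
    """

    params: ModelParams
    species: list[SpeciesState] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = self.params.L
        for k, sp in enumerate(self.species):
            if sp.L != L:
                raise ValueError(
                    f"species {k} has trait dimension {sp.L}, expected {L}"
                )

    @property
    def S(self) -> int:
        return len(self.species)

    def frequencies(self) -> np.ndarray:
        """Relative frequencies ``f_i = N_i / sum_j N_j``."""
        N = np.array([sp.N for sp in self.species], dtype=float)
        total = N.sum()
        if total <= 0:
            raise ValueError("total density is zero; frequencies undefined")
        return N / total

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Stacked state arrays ``(N, mu, G, E)`` with leading species axis."""
        N = np.array([sp.N for sp in self.species], dtype=float)
        mu = np.stack([sp.mu for sp in self.species]) if self.species else np.empty((0, self.params.L))
        G = np.stack([sp.G for sp in self.species]) if self.species else np.empty((0, self.params.L, self.params.L))
        E = np.stack([sp.E for sp in self.species]) if self.species else np.empty((0, self.params.L, self.params.L))
        return N, mu, G, E

    def copy(self) -> "Community":
        return Community(self.params, [sp.copy() for sp in self.species])

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d["species"] = [sp.to_dict() for sp in self.species]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Community":
        params = ModelParams.from_dict(d)
        return cls(params, [SpeciesState.from_dict(s) for s in d.get("species", [])])

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Community":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# closed-form operations
# ---------------------------------------------------------------------------


def mortality(params: ModelParams, z) -> np.ndarray | float:
    """Intrinsic mortality ``m(z)``; accepts a trait vector or an array of them.

    ``m(z) = (z.z)/theta^2`` (quadratic) or ``(z.z)^2/theta^4`` (quartic).
    """
    z = np.asarray(z, dtype=float)
    if z.shape[-1:] != (params.L,):
        raise ValueError(
            f"trait vector has trailing dimension {z.shape[-1] if z.ndim else 0}, "
            f"expected L={params.L}"
        )
    zz = np.sum(z * z, axis=-1)
    if params.mortality_shape == "quadratic":
        out = zz / params.theta**2
    else:
        out = zz**2 / params.theta**4
    return float(out) if out.ndim == 0 else out


def intrinsic_growth(params: ModelParams, z) -> np.ndarray | float:
    """Per-capita growth of phenotype ``z`` in the absence of competition.

    The resource-intake integral of the consumer-resource derivation equals 1
    identically for the Gaussian utilization / supply normalization, so this is
    simply ``1 - m(z)``.
    """
    return 1.0 - mortality(params, z)


def competition_kernel(params: ModelParams, d) -> np.ndarray | float:
    """Competition coefficient between point phenotypes separated by ``d``.

    The resource-overlap integral of two Gaussian utilization curves reduces
    to ``exp(-|d|^2/omega^2)``: symmetric, in (0, 1], equal to 1 iff d = 0.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[-1:] != (params.L,):
        raise ValueError(
            f"displacement has trailing dimension {d.shape[-1] if d.ndim else 0}, "
            f"expected L={params.L}"
        )
    out = np.exp(-np.sum(d * d, axis=-1) / params.omega**2)
    return float(out) if out.ndim == 0 else out


def _logdet_pd(M: np.ndarray) -> float:
    """log det of a symmetric PD matrix via eigendecomposition with a floor."""
    vals = np.linalg.eigvalsh(M)
    if vals[0] < EIG_FLOOR:
        warnings.warn(
            f"covariance eigenvalue {vals[0]:.3e} below floor; clamped to {EIG_FLOOR}",
            RuntimeWarning,
            stacklevel=3,
        )
        vals = np.clip(vals, EIG_FLOOR, None)
    return float(np.sum(np.log(vals)))


def _alpha(params: ModelParams, mu_a, P_a, mu_b, P_b) -> float:
    """Competition coefficient between two Gaussian phenotype clouds.

    ``alpha = sqrt(det(2W)/det(B)) * exp(-0.5 dmu^T B^-1 dmu)`` with
    ``B = 2W + P_a + P_b``; in 1-D this is
    ``omega/sqrt(omega^2+2P_a+2P_b) * exp(-dmu^2/(omega^2+2P_a+2P_b))``.
    """
    L = params.L
    B = (params.omega**2 / 2.0) * np.eye(L) + P_a + P_b
    dmu = np.asarray(mu_a, dtype=float) - np.asarray(mu_b, dtype=float)
    logdet2W = L * np.log(params.omega**2 / 2.0)
    quad = float(dmu @ np.linalg.solve(B, dmu))
    return float(np.exp(0.5 * (logdet2W - _logdet_pd(B)) - 0.5 * quad))


def pairwise_competition(
    params: ModelParams, a: SpeciesState, b: SpeciesState
) -> float:
    """Competition coefficient ``alpha_ab`` between two species.

    Averages the point-phenotype kernel over both species' trait
    distributions; symmetric, in (0, 1], decreasing in mean separation and in
    total phenotypic variance.  Accepts singular ``P`` (point phenotypes).
    """
    if a.L != params.L or b.L != params.L:
        raise ValueError(f"species trait dimension must equal L={params.L}")
    for name, P in (("P_a", a.P), ("P_b", b.P)):
        if _min_eig(P) < -1e-9:
            raise ValueError(f"{name} must be positive semidefinite")
    return _alpha(params, a.mu, a.P, b.mu, b.P)


def fitness_landscape(community: Community, z) -> np.ndarray | float:
    """Per-capita growth rate ``r(z)`` of phenotype ``z`` in the community.

    ``r(z) = 1 - m(z) - sum_j N_j <a>_{p_j}(z)`` where ``<a>_{p_j}`` is the
    competition kernel averaged over species j's phenotype distribution,
    itself a Gaussian of ``z``.  Vectorized over a trailing-``L`` array of
    trait vectors.  An empty community reduces to the intrinsic growth rate.
    """
    params = community.params
    z = np.asarray(z, dtype=float)
    r = np.asarray(intrinsic_growth(params, z), dtype=float)
    L = params.L
    W2 = (params.omega**2 / 2.0) * np.eye(L)
    logdet2W = L * np.log(params.omega**2 / 2.0)
    for sp in community.species:
        if sp.N == 0.0:
            continue
        A = W2 + sp.P
        diff = z - sp.mu
        quad = np.einsum("...k,kl,...l->...", diff, np.linalg.inv(A), diff)
        c = np.exp(0.5 * (logdet2W - _logdet_pd(A)))
        r = r - sp.N * c * np.exp(-0.5 * quad)
    return float(r) if r.ndim == 0 else r


def _mortality_moments(
    params: ModelParams, mu: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian expectations of m(z), (z-mu) m(z), and ((z-mu)(z-mu)^T - P) m(z).

    Batched over a leading species axis: ``mu`` is (S, L), ``P`` is (S, L, L).
    Closed forms follow from Isserlis' theorem for Gaussian moments up to
    order six (quartic mortality).
    """
    th2 = params.theta**2
    mumu = np.einsum("ik,ik->i", mu, mu)  # |mu|^2
    trP = np.trace(P, axis1=1, axis2=2)
    Pmu = np.einsum("ikl,il->ik", P, mu)
    if params.mortality_shape == "quadratic":
        m0 = (mumu + trP) / th2
        m1 = 2.0 * Pmu / th2
        m2 = 2.0 * np.einsum("ikl,ilm->ikm", P, P) / th2
        return m0, m1, m2
    th4 = params.theta**4
    P2 = np.einsum("ikl,ilm->ikm", P, P)
    P3 = np.einsum("ikl,ilm->ikm", P2, P)
    muPmu = np.einsum("ik,ik->i", mu, Pmu)
    s = mumu + trP
    m0 = (s**2 + 2.0 * np.trace(P2, axis1=1, axis2=2) + 4.0 * muPmu) / th4
    m1 = (4.0 * s[:, None] * Pmu + 8.0 * np.einsum("ikl,il->ik", P2, mu)) / th4
    m2 = (
        8.0 * np.einsum("ik,il->ikl", Pmu, Pmu)
        + 4.0 * s[:, None, None] * P2
        + 8.0 * P3
    ) / th4
    return m0, m1, m2


def _moments_arrays(
    params: ModelParams, N: np.ndarray, mu: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form growth-rate moments for every species at once.

    Returns, for each species i, the Gaussian expectations over ``p_i`` of

    * ``m0_i = E[r(z)]`` — mean fitness,
    * ``m1_i = E[(z - mu_i) r(z)]`` — selection differential, and
    * ``M2_i = (1/2) E[((z-mu_i)(z-mu_i)^T - P_i) r(z)]`` — selection on
      (co)variances,

    with ``r`` the community fitness landscape (species i's own competition
    term included, as in the model).  Shapes: (S,), (S, L), (S, L, L).
    """
    S, L = mu.shape
    if S == 0:
        return np.empty(0), np.empty((0, L)), np.empty((0, L, L))
    W2 = (params.omega**2 / 2.0) * np.eye(L)
    # pairwise Gaussian overlap: B_ij = 2W + P_i + P_j
    B = W2[None, None] + P[:, None] + P[None, :]
    Binv = np.linalg.inv(B)
    _, logdetB = np.linalg.slogdet(B)
    logdet2W = L * np.log(params.omega**2 / 2.0)
    delta = mu[:, None, :] - mu[None, :, :]
    quad = np.einsum("ijk,ijkl,ijl->ij", delta, Binv, delta)
    alpha = np.exp(0.5 * (logdet2W - logdetB) - 0.5 * quad)

    v = np.einsum("ijkl,ijl->ijk", Binv, delta)  # B_ij^-1 (mu_i - mu_j)
    Pv = np.einsum("ikl,ijl->ijk", P, v)  # P_i B_ij^-1 (mu_i - mu_j)
    PBP = np.einsum("ikl,ijlm,imn->ijkn", P, Binv, P)  # P_i B_ij^-1 P_i
    PvvP = np.einsum("ijk,ijl->ijkl", Pv, Pv)

    Em0, Em1, Em2 = _mortality_moments(params, mu, P)
    m0 = 1.0 - Em0 - alpha @ N
    m1 = -Em1 + np.einsum("ij,j,ijk->ik", alpha, N, Pv)
    M2 = 0.5 * (-Em2 - np.einsum("ij,j,ijkl->ikl", alpha, N, PvvP - PBP))
    M2 = 0.5 * (M2 + np.swapaxes(M2, 1, 2))
    return m0, m1, M2


def fitness_moments(
    community: Community, i: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fitness moments of species ``i``: the three integrals driving Eqs. of motion.

    Returns ``(m0, m1, M2)`` — the mean growth rate, the selection
    differential ``E[(z - mu_i) r(z)]``, and half the expectation of
    ``((z-mu_i)(z-mu_i)^T - P_i) r(z)`` under species i's trait distribution.
    """
    if not 0 <= i < community.S:
        raise IndexError(f"species index {i} out of range for S={community.S}")
    N, mu, G, E = community.arrays()
    P = G + E
    if _min_eig(P[i]) < EIG_FLOOR:
        raise ValueError(
            "P_i = G_i + E_i is singular; supply a positive-definite "
            "environmental covariance E (minimum eigenvalue > 1e-12)"
        )
    m0, m1, M2 = _moments_arrays(community.params, N, mu, P)
    return float(m0[i]), m1[i], M2[i]
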