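"""Time integration of the coupled density / trait-mean / G-matrix dynamics.

The equations of motion are, per species,

    dN_i/dt  = N_i * m0_i
    dmu_i/dt = G_i P_i^-1 m1_i
    dG_i/dt  = G_i P_i^-1 M2_i P_i^-1 G_i

with ``(m0, m1, M2)`` the closed-form fitness moments of
:mod:`ecoevodiv.model`.  The flow is stiff over long horizons (selection on
variances slows down quadratically as G -> 0), so integration uses an adaptive
implicit-capable solver (LSODA) in segments between logarithmically spaced
checkpoints, stopping early once the derivative norm falls below a threshold.

The *null model* is the identical system with dG/dt forced to zero, so only
densities and trait means evolve while trait covariances stay frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import Community, ModelParams, SpeciesState, _moments_arrays

__all__ = [
    "IntegratorOptions",
    "Trajectory",
    "IntegrationError",
    "rhs",
    "integrate",
    "run_null",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid state and time reached."""

    def __init__(self, message: str, last_state: Community, t: float):
        super().__init__(message)
        self.last_state = last_state
        self.t = t


@dataclass(frozen=True)
class IntegratorOptions:
    """Integration controls.

    ``t_end`` defaults to 1e10 time units — long enough for the model
    communities to reach an eco-evolutionarily stable equilibrium; with
    ``equilibrium_tol`` early stopping most runs terminate far sooner.
    ``extinction_threshold`` only tags species for reporting; species are
    never removed from the state.  ``seed`` is recorded for bookkeeping (the
    dynamics themselves are deterministic).
    """

    t_end: float = 1e10
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    equilibrium_tol: float = 1e-10
    extinction_threshold: float = 1e-6
    freeze_G: bool = False
    n_snapshots: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.equilibrium_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Trajectory:
    """Snapshots of a community along an integration."""

    times: np.ndarray
    states: list[Community]
    converged: bool
    t_final: float

    @property
    def final(self) -> Community:
        return self.states[-1]


# ---------------------------------------------------------------------------
# state packing: per species [N, mu (L), upper triangle of G (L(L+1)/2)]
# ---------------------------------------------------------------------------


def _pack(N: np.ndarray, mu: np.ndarray, G: np.ndarray, iu) -> np.ndarray:
    S = N.shape[0]
    return np.concatenate(
        [N[:, None], mu, G[:, iu[0], iu[1]]], axis=1
    ).reshape(S * (1 + mu.shape[1] + iu[0].size))


def _unpack(y: np.ndarray, S: int, L: int, iu):
    T = iu[0].size
    blk = y.reshape(S, 1 + L + T)
    N = blk[:, 0]
    mu = blk[:, 1 : 1 + L]
    G = np.zeros((S, L, L))
    G[:, iu[0], iu[1]] = blk[:, 1 + L :]
    G[:, iu[1], iu[0]] = blk[:, 1 + L :]
    return N, mu, G


def _rhs_arrays(
    params: ModelParams,
    N: np.ndarray,
    mu: np.ndarray,
    G: np.ndarray,
    E: np.ndarray,
    freeze_G: bool,
):
    P = G + E
    m0, m1, M2 = _moments_arrays(params, np.maximum(N, 0.0), mu, P)
    dN = N * m0
    x = np.linalg.solve(P, m1[..., None])[..., 0]  # P^-1 m1
    dmu = np.einsum("ikl,il->ik", G, x)
    if freeze_G:
        dG = np.zeros_like(G)
    else:
        K = np.linalg.solve(P, M2)  # P^-1 M2
        A = np.swapaxes(np.linalg.solve(P, np.swapaxes(K, 1, 2)), 1, 2)  # P^-1 M2 P^-1
        dG = np.einsum("ikl,ilm,imn->ikn", G, A, G)
        dG = 0.5 * (dG + np.swapaxes(dG, 1, 2))
    return dN, dmu, dG


def rhs(community: Community, freeze_G: bool = False):
    """Right-hand sides ``(dN, dmu, dG)`` of the equations of motion.

    ``dN`` has shape (S,), ``dmu`` (S, L), ``dG`` (S, L, L); each ``dG_i`` is
    symmetric, and vanishes identically when ``G_i = 0`` or under
    ``freeze_G`` (the null model).
    """
    N, mu, G, E = community.arrays()
    P = G + E
    if community.S and np.linalg.eigvalsh(P).min() < 1e-12:
        raise ValueError(
            "singular phenotypic covariance P = G + E; "
            "the dynamics require positive-definite E"
        )
    return _rhs_arrays(community.params, N, mu, G, E, freeze_G)


def _project_psd(G: np.ndarray, floor: float) -> np.ndarray:
    """Clamp small negative round-off eigenvalues of each G_i to zero.

    Eigenvalues below ``-floor`` indicate a genuine solver failure (the exact
    flow preserves positive semidefiniteness) and raise.
    """
    vals, vecs = np.linalg.eigh(G)
    if vals.min() < -floor:
        raise IntegrationError(
            f"genetic covariance eigenvalue {vals.min():.3e} below -{floor:.1e}; "
            "integration tolerance too loose",
            last_state=None,  # filled by caller
            t=np.nan,
        )
    vals = np.clip(vals, 0.0, None)
    return np.einsum("ikl,il,iml->ikm", vecs, vals, vecs)


def _community_from_arrays(
    params: ModelParams, N, mu, G, E
) -> Community:
    species = [
        SpeciesState(N=max(float(N[i]), 0.0), mu=mu[i].copy(), G=G[i].copy(), E=E[i].copy())
        for i in range(N.shape[0])
    ]
    return Community(params, species)


def integrate(
    community: Community, options: IntegratorOptions | None = None
) -> Trajectory:
    """Integrate a community to eco-evolutionary equilibrium.

    Proceeds through logarithmically spaced checkpoints up to
    ``options.t_end``; at each checkpoint the genetic covariances are
    projected back onto the PSD cone (round-off only) and the derivative
    max-norm is tested against ``options.equilibrium_tol`` for early
    stopping.  Returns a :class:`Trajectory` whose last state is the final
    (possibly equilibrated) community.
    """
    opts = options or IntegratorOptions()
    params = community.params
    S, L = community.S, params.L
    if S == 0:
        raise ValueError("cannot integrate an empty community")
    N0, mu0, G0, E = community.arrays()
    if np.linalg.eigvalsh(G0 + E).min() < 1e-12:
        raise ValueError("P = G + E must be positive definite to integrate")
    iu = np.triu_indices(L)
    psd_floor = max(100.0 * opts.abs_tol, 1e-12)

    def f(t, y):
        N, mu, G = _unpack(y, S, L, iu)
        dN, dmu, dG = _rhs_arrays(params, N, mu, G, E, opts.freeze_G)
        return _pack(dN, dmu, dG, iu)

    # checkpoint grid: log-spaced from the first unit of time outward
    t0 = min(1.0, opts.t_end / 10.0)
    n_log = max(opts.n_snapshots - 1, 2)
    checkpoints = np.unique(
        np.concatenate([[0.0], np.geomspace(t0, opts.t_end, n_log)])
    )

    times = [0.0]
    states = [community.copy()]
    y = _pack(N0, mu0, G0, iu)
    converged = False
    t_prev = 0.0
    for t_next in checkpoints[1:]:
        sol = solve_ivp(
            f,
            (t_prev, t_next),
            y,
            method="LSODA",
            rtol=opts.rel_tol,
            atol=opts.abs_tol,
            dense_output=False,
        )
        N, mu, G = _unpack(sol.y[:, -1], S, L, iu)
        if not sol.success:
            raise IntegrationError(
                f"solver failed at t={sol.t[-1]:.6g}: {sol.message}",
                last_state=_community_from_arrays(
                    params, np.maximum(N, 0), mu, _project_psd(G, np.inf), E
                ),
                t=float(sol.t[-1]),
            )
        try:
            G = _project_psd(G, psd_floor)
        except IntegrationError as err:
            err.last_state = _community_from_arrays(params, N, mu, G, E)
            err.t = float(sol.t[-1])
            raise
        N = np.maximum(N, 0.0)
        y = _pack(N, mu, G, iu)
        t_prev = float(sol.t[-1])
        times.append(t_prev)
        states.append(_community_from_arrays(params, N, mu, G, E))
        dN, dmu, dG = _rhs_arrays(params, N, mu, G, E, opts.freeze_G)
        norm = max(
            np.abs(dN).max(initial=0.0),
            np.abs(dmu).max(initial=0.0),
            np.abs(dG).max(initial=0.0),
        )
        if norm < opts.equilibrium_tol:
            converged = True
            break

    return Trajectory(
        times=np.asarray(times),
        states=states,
        converged=converged,
        t_final=t_prev,
    )


def run_null(
    community: Community, options: IntegratorOptions | None = None
) -> Trajectory:
    """Integrate the frozen-covariance null model.

    Identical to :func:`integrate` except that trait covariances are not
    allowed to evolve (``dG/dt = 0``); provided as a named entry point so
    experiment outputs can label null runs.
    """
    opts = options or IntegratorOptions()
    return integrate(community, replace(opts, freeze_G=True))


def extant_mask(community: Community, threshold: float = 1e-6) -> np.ndarray:
    """Boolean mask of species whose density exceeds the extinction threshold."""
    N = np.array([sp.N for sp in community.species])
    return N > threshold
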