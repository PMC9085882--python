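"""Factorial simulation protocol: design grid, seeded initial conditions, batches.

The full design crosses trait dimensionality L in {1,2,3}, initial species
number S0 in {2..25}, two initial genetic-covariance levels, three
environmental-covariance levels, two competition widths (resolved per L so
higher-dimensional trait spaces get wider kernels), and two mortality shapes:
3 x 24 x 2 x 3 x 2 x 2 = 1728 unique combinations, each run in 10 seeded
replicates by default.  Every design point is run twice from bit-identical
initial conditions — the full model and the frozen-covariance null model —
and summarized into one tidy row per (point, model).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ortho_group

from .dynamics import IntegratorOptions, Trajectory, integrate, run_null
from .metrics import GridSpec, functional_diversity, hill_number, resource_depletion, total_biomass
from .model import Community, ModelParams, SpeciesState

__all__ = [
    "G_LEVELS",
    "E_LEVELS",
    "OMEGA_LEVELS",
    "DesignPoint",
    "ResultRow",
    "build_design",
    "expand_replicates",
    "sample_initial_G",
    "sample_initial_community",
    "run_batch",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

#: initial genetic trait-SD ranges (trait units); G eigenvalues are their squares
G_LEVELS: dict[str, tuple[float, float]] = {
    "low": (0.01, 0.05),
    "high": (0.05, 0.1),
}

#: environmental trait-SD ranges (trait units); E diagonal entries are their squares
E_LEVELS: dict[str, tuple[float, float]] = {
    "low": (0.005, 0.008),
    "medium": (0.015, 0.018),
    "high": (0.025, 0.028),
}

#: competition width per (trait dimensionality, level)
OMEGA_LEVELS: dict[int, dict[str, float]] = {
    1: {"low": 0.1, "high": 0.15},
    2: {"low": 0.25, "high": 0.3},
    3: {"low": 0.4, "high": 0.45},
}

L_VALUES: tuple[int, ...] = (1, 2, 3)
S0_VALUES: tuple[int, ...] = tuple(range(2, 26))
MORTALITY_SHAPES: tuple[str, ...] = ("quadratic", "quartic")
THETA: float = 0.5


@dataclass(frozen=True)
class DesignPoint:
    """One cell of the factorial design (optionally one seeded replicate of it)."""

    L: int
    S0: int
    g_level: str
    e_level: str
    omega_level: str
    mortality_shape: str
    replicate: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.L not in OMEGA_LEVELS:
            raise ValueError(f"L must be one of {sorted(OMEGA_LEVELS)}")
        if self.g_level not in G_LEVELS:
            raise ValueError(f"g_level must be one of {sorted(G_LEVELS)}")
        if self.e_level not in E_LEVELS:
            raise ValueError(f"e_level must be one of {sorted(E_LEVELS)}")
        if self.omega_level not in OMEGA_LEVELS[self.L]:
            raise ValueError(
                f"omega_level must be one of {sorted(OMEGA_LEVELS[self.L])}"
            )
        if self.mortality_shape not in MORTALITY_SHAPES:
            raise ValueError(f"mortality_shape must be one of {MORTALITY_SHAPES}")

    @property
    def omega(self) -> float:
        return OMEGA_LEVELS[self.L][self.omega_level]

    def params(self) -> ModelParams:
        return ModelParams(
            L=self.L,
            omega=self.omega,
            theta=THETA,
            mortality_shape=self.mortality_shape,
        )


@dataclass(frozen=True)
class ResultRow:
    """Summary of one run: design fields plus equilibrium diversities and functions."""

    L: int
    S0: int
    g_level: str
    e_level: str
    omega_level: str
    mortality_shape: str
    replicate: int | None
    seed: int | None
    model: str  # "full" or "null"
    t_final: float
    converged: bool
    species_diversity: float
    functional_diversity: float
    total_biomass: float
    resource_depletion: float
    n_extant: int


def build_design(
    L_values: Sequence[int] = L_VALUES,
    S0_values: Sequence[int] = S0_VALUES,
    g_levels: Sequence[str] = tuple(G_LEVELS),
    e_levels: Sequence[str] = tuple(E_LEVELS),
    omega_levels: Sequence[str] = ("low", "high"),
    mortality_shapes: Sequence[str] = MORTALITY_SHAPES,
) -> list[DesignPoint]:
    """The full factorial product of design factors, without replicates.

    Deterministic lexicographic order in (L, S0, g_level, e_level,
    omega_level, mortality_shape); the default arguments yield the complete
    1728-point grid.
    """
    return [
        DesignPoint(L=L, S0=S0, g_level=g, e_level=e, omega_level=w, mortality_shape=m)
        for L, S0, g, e, w, m in itertools.product(
            L_values, S0_values, g_levels, e_levels, omega_levels, mortality_shapes
        )
    ]


def expand_replicates(
    design: Iterable[DesignPoint], n_replicates: int = 10, master_seed: int = 0
) -> list[DesignPoint]:
    """Attach replicate indices and per-run seeds derived from a master seed.

    Seeds are generated with a counter-based scheme — ``SeedSequence(master_seed)``
    spawned per (design index, replicate) — so any run is reproducible from
    (master seed, row index) alone and batches can execute in any order.
    """
    points = list(design)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(points) * n_replicates)
    out = []
    k = 0
    for pt in points:
        for rep in range(1, n_replicates + 1):
            seed = int(children[k].generate_state(1, dtype=np.uint32)[0] % (2**31))
            out.append(replace(pt, replicate=rep, seed=seed))
            k += 1
    return out


def sample_initial_G(
    L: int, level: str, rng: np.random.Generator
) -> np.ndarray:
    """Random initial genetic covariance ``U B U^T``.

    ``U`` is Haar-uniform orthogonal and ``B`` diagonal with each entry the
    square of a trait standard deviation drawn uniformly from the level's
    range ([0.01, 0.05] low, [0.05, 0.1] high, in trait units) — so genetic
    breadths start well below the competition width and the environmental
    floor stays far smaller than omega, the regime where selection against
    niche overlap can act.  The result is symmetric PSD with eigenvalue
    square roots in the level range.  For L = 1 the orthogonal group is
    {±1}, so this is a scalar draw.
    """
    a, b = G_LEVELS[level]
    vals = rng.uniform(a, b, size=L) ** 2
    if L == 1:
        return np.array([[vals[0]]])
    U = ortho_group.rvs(L, random_state=rng)
    return U @ np.diag(vals) @ U.T


def sample_initial_community(
    point: DesignPoint, rng: np.random.Generator
) -> Community:
    """Seeded initial community for one design point.

    S0 species, each with density 1, trait mean components uniform on
    [-0.5, 0.5], genetic covariance from :func:`sample_initial_G`, and a
    diagonal environmental covariance whose entries are squares of trait
    standard deviations uniform in the e-level range.  All random components
    are drawn fresh per replicate.
    """
    params = point.params()
    e_lo, e_hi = E_LEVELS[point.e_level]
    species = []
    for _ in range(point.S0):
        mu = rng.uniform(-0.5, 0.5, size=point.L)
        G = sample_initial_G(point.L, point.g_level, rng)
        E = np.diag(rng.uniform(e_lo, e_hi, size=point.L) ** 2)
        species.append(SpeciesState(N=1.0, mu=mu, G=G, E=E))
    return Community(params, species)


def _summarize(
    point: DesignPoint,
    model: str,
    traj: Trajectory | None,
    options: IntegratorOptions,
    grid: GridSpec,
    q: float,
) -> ResultRow:
    if traj is None:
        return ResultRow(
            **_point_fields(point), model=model, t_final=np.nan, converged=False,
            species_diversity=np.nan, functional_diversity=np.nan,
            total_biomass=np.nan, resource_depletion=np.nan, n_extant=0,
        )
    final = traj.final
    N = np.array([sp.N for sp in final.species])
    return ResultRow(
        **_point_fields(point),
        model=model,
        t_final=traj.t_final,
        converged=traj.converged,
        species_diversity=hill_number(final.frequencies(), q),
        functional_diversity=functional_diversity(final, q, grid),
        total_biomass=total_biomass(final),
        resource_depletion=resource_depletion(final),
        n_extant=int((N > options.extinction_threshold).sum()),
    )


def _point_fields(point: DesignPoint) -> dict:
    return {
        "L": point.L,
        "S0": point.S0,
        "g_level": point.g_level,
        "e_level": point.e_level,
        "omega_level": point.omega_level,
        "mortality_shape": point.mortality_shape,
        "replicate": point.replicate,
        "seed": point.seed,
    }


def run_batch(
    design: Iterable[DesignPoint],
    options: IntegratorOptions | None = None,
    q: float = 2.0,
    grid_bins: int = 101,
) -> list[ResultRow]:
    """Run every seeded design point under the full and null models.

    For each point the initial community is drawn once from the point's seed,
    then integrated twice from bit-identical initial conditions: the full
    model and the frozen-covariance null model.  Individual run failures are
    logged and recorded as unconverged rows; they never abort the batch.
    Returns two :class:`ResultRow` per point, full before null.
    """
    opts = options or IntegratorOptions()
    rows: list[ResultRow] = []
    for point in design:
        if point.seed is None:
            raise ValueError(
                "design points must carry seeds; use expand_replicates() first"
            )
        rng = np.random.default_rng(point.seed)
        community = sample_initial_community(point, rng)
        grid = GridSpec(L=point.L, bins_per_dim=grid_bins)
        for model, runner in (("full", integrate), ("null", run_null)):
            try:
                traj = runner(community.copy(), opts)
            except Exception:
                logger.exception(
                    "run failed (model=%s, point=%s); recording unconverged row",
                    model, point,
                )
                traj = None
            rows.append(_summarize(point, model, traj, opts, grid, q))
    return rows


def results_to_frame(rows: Iterable[ResultRow]) -> pd.DataFrame:
    """Tidy DataFrame of batch results, one row per (design point, model)."""
    return pd.DataFrame([asdict(r) for r in rows])
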