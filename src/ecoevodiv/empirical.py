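"""Individual-level trait-table pipeline for isolated island subcommunities.

Input is a table of individuals — species identity, subcommunity (island code
plus arid/humid vegetation zone), and two continuous shell traits (centroid
size and shape PC1) — together with per-subcommunity counts of available host
plant species.  Because species ranges never span both vegetation zones, each
(island, zone) pair is treated as an independent community.

The pipeline: clean the table (drop excluded islands and under-sampled
species), fit a per-species bivariate trait density (binormal maximum
likelihood or KDE) in a shared trait frame rescaled to [-1, 1] per axis,
merge densities into an abundance-weighted community trait density, compute
functional diversity on a regular grid, compute Hill-q2 species diversity
normalized by host-plant count, regress functional diversity on normalized
species diversity, and test the regression's sign against randomized relative
abundances (the recorded abundances reflect sampling effort, not true
densities).  A synthetic fixture generator emulates this data structure with
known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde

from .metrics import GridSpec, functional_diversity_from_values, hill_number

__all__ = [
    "TRAIT_COLUMNS",
    "TraitTable",
    "CleaningReport",
    "SubcommunitySummary",
    "RegressionResult",
    "RandomizationResult",
    "BinormalDensity",
    "KDEDensity",
    "clean",
    "fit_species_density",
    "subcommunity_summary",
    "sd_fd_regression",
    "abundance_randomization",
    "generate_fixture",
]

TRAIT_COLUMNS = ("size", "shapePC1")
REQUIRED_COLUMNS = ("species", "island", "zone") + TRAIT_COLUMNS
ZONES = ("arid", "humid")

DEFAULT_EXCLUDED_ISLANDS = frozenset({"CH", "ED", "GA"})


@dataclass
class TraitTable:
    """Individual-level records plus per-subcommunity host-plant counts.

    ``data`` has one row per individual with columns
    (species, island, zone, size, shapePC1); ``host_plants`` maps each
    (island, zone) subcommunity to its positive host-plant species count.
    """

    data: pd.DataFrame
    host_plants: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        bad_zone = set(self.data["zone"]) - set(ZONES)
        if bad_zone:
            raise ValueError(f"unknown vegetation zones: {sorted(bad_zone)}")
        traits = self.data[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(traits).all():
            raise ValueError("trait values must be finite")
        keys = set(map(tuple, self.data[["island", "zone"]].itertuples(index=False)))
        missing_hp = keys - set(self.host_plants)
        if missing_hp:
            raise ValueError(f"host_plants missing subcommunities: {sorted(missing_hp)}")
        for k, v in self.host_plants.items():
            if not v > 0:
                raise ValueError(f"host-plant count for {k} must be positive")

    @property
    def subcommunities(self) -> list[tuple[str, str]]:
        return sorted(
            set(map(tuple, self.data[["island", "zone"]].itertuples(index=False)))
        )

    @classmethod
    def from_csv(cls, traits_path: str | Path, hostplants_path: str | Path) -> "TraitTable":
        """Load from a trait CSV (species,island,zone,size,shapePC1) and a
        host-plant CSV (island,zone,n_hostplants)."""
        data = pd.read_csv(traits_path)
        hp = pd.read_csv(hostplants_path)
        host_plants = {
            (str(r.island), str(r.zone)): int(r.n_hostplants)
            for r in hp.itertuples(index=False)
        }
        return cls(data=data, host_plants=host_plants)


@dataclass(frozen=True)
class CleaningReport:
    """Counts of records dropped by each cleaning rule."""

    n_input: int
    n_island_excluded: int
    n_rare_species_excluded: int
    n_kept: int
    excluded_islands: tuple[str, ...]
    excluded_species: tuple[str, ...]


def clean(
    table: TraitTable,
    excluded_islands: frozenset[str] | set[str] = DEFAULT_EXCLUDED_ISLANDS,
    min_individuals: int = 3,
) -> tuple[TraitTable, CleaningReport]:
    """Drop excluded islands and species sampled below ``min_individuals``.

    The defaults drop the three small satellite islands (CH, ED, GA) and any
    species with fewer than 3 individuals in the whole dataset (3 being the
    minimum for a maximum-likelihood binormal fit).  Returns the cleaned
    table and a report of what each rule removed.
    """
    df = table.data
    n_input = len(df)
    island_mask = df["island"].isin(excluded_islands)
    df2 = df.loc[~island_mask]
    counts = df2["species"].value_counts()
    rare = counts[counts < min_individuals].index
    rare_mask = df2["species"].isin(rare)
    df3 = df2.loc[~rare_mask].reset_index(drop=True)
    if df3.empty:
        raise ValueError("no records remain after cleaning")
    hp = {
        k: v
        for k, v in table.host_plants.items()
        if k[0] not in excluded_islands
        and k in set(map(tuple, df3[["island", "zone"]].itertuples(index=False)))
    }
    report = CleaningReport(
        n_input=n_input,
        n_island_excluded=int(island_mask.sum()),
        n_rare_species_excluded=int(rare_mask.sum()),
        n_kept=len(df3),
        excluded_islands=tuple(sorted(set(df["island"]) & set(excluded_islands))),
        excluded_species=tuple(sorted(rare)),
    )
    return TraitTable(data=df3, host_plants=hp), report


# ---------------------------------------------------------------------------
# species-level density estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinormalDensity:
    """Bivariate normal trait density with ML (1/n) parameter estimates."""

    mean: np.ndarray
    cov: np.ndarray

    def pdf(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        diff = pts - self.mean
        cinv = np.linalg.inv(self.cov)
        quad = np.einsum("nk,kl,nl->n", diff, cinv, diff)
        norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(self.cov)))
        return norm * np.exp(-0.5 * quad)


@dataclass(frozen=True)
class KDEDensity:
    """Gaussian kernel density estimate of the trait cloud."""

    kde: gaussian_kde

    def pdf(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.kde(pts.T)


def fit_species_density(
    points: np.ndarray, method: str = "binormal_mle", bw_method=None
):
    """Fit one species' 2-D trait density.

    ``binormal_mle`` fits a bivariate normal with the sample mean and the
    maximum-likelihood (1/n) covariance (requires >= 3 individuals and a
    nonsingular scatter); ``kde`` fits a Gaussian kernel density estimate
    with a plug-in bandwidth (requires >= 2 individuals).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of trait values")
    n = pts.shape[0]
    if method == "binormal_mle":
        if n < 3:
            raise ValueError("binormal_mle needs at least 3 individuals")
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T, ddof=0)
        if np.linalg.det(cov) <= 1e-300 or np.linalg.eigvalsh(cov)[0] <= 0:
            raise ValueError(
                "sample covariance is singular (e.g. identical points); "
                "try method='kde'"
            )
        return BinormalDensity(mean=mean, cov=cov)
    if method == "kde":
        if n < 2:
            raise ValueError("kde needs at least 2 individuals")
        try:
            return KDEDensity(kde=gaussian_kde(pts.T, bw_method=bw_method))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"kde failed on degenerate trait cloud: {err}") from err
    raise ValueError(f"unknown density method {method!r}")


# ---------------------------------------------------------------------------
# subcommunity summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubcommunitySummary:
    """Diversity summary of one (island, zone) subcommunity."""

    island: str
    zone: str
    S: int
    n_individuals: int
    species_diversity_q2: float
    host_plants: int
    normalized_diversity: float
    functional_diversity: float


@dataclass
class _FittedSubcommunity:
    island: str
    zone: str
    species: list[str]
    counts: np.ndarray
    density_grids: np.ndarray  # (S, C) species densities at grid centers
    host_plants: int
    n_individuals: int


def _shared_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-axis (min, max) over the whole cleaned dataset."""
    traits = df[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    lo, hi = traits.min(axis=0), traits.max(axis=0)
    if (hi <= lo).any():
        raise ValueError("degenerate trait range; cannot build a shared frame")
    return lo, hi


def _rescale(traits: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Affine map of each axis from [lo, hi] to [-1, 1]."""
    return 2.0 * (traits - lo) / (hi - lo) - 1.0


def _fit_subcommunities(
    table: TraitTable,
    grid: GridSpec,
    density_method: str,
    min_individuals: int,
) -> list[_FittedSubcommunity]:
    """Rescale traits to the shared frame and fit per-species grid densities.

    All subcommunities share one trait frame (pooled min/max mapped to
    [-1, 1] per axis) so functional diversities are comparable across them.
    Species with fewer than ``min_individuals`` records inside a
    subcommunity are dropped from it with a warning; a subcommunity left
    with no usable species is excluded with a warning.
    """
    lo, hi = _shared_frame(table.data)
    centers = grid.centers()
    fitted: list[_FittedSubcommunity] = []
    for island, zone in table.subcommunities:
        sub = table.data[(table.data["island"] == island) & (table.data["zone"] == zone)]
        names, counts, grids = [], [], []
        for sp, group in sub.groupby("species", sort=True):
            pts = _rescale(group[list(TRAIT_COLUMNS)].to_numpy(dtype=float), lo, hi)
            if len(pts) < min_individuals:
                warnings.warn(
                    f"species {sp!r} has {len(pts)} < {min_individuals} individuals "
                    f"in ({island}, {zone}); dropped from that subcommunity",
                    stacklevel=3,
                )
                continue
            dens = fit_species_density(pts, method=density_method)
            names.append(sp)
            counts.append(len(pts))
            grids.append(dens.pdf(centers))
        if not names:
            warnings.warn(
                f"subcommunity ({island}, {zone}) has no species with "
                f">= {min_individuals} individuals; excluded",
                stacklevel=3,
            )
            continue
        fitted.append(
            _FittedSubcommunity(
                island=island,
                zone=zone,
                species=names,
                counts=np.array(counts, dtype=float),
                density_grids=np.stack(grids),
                host_plants=table.host_plants[(island, zone)],
                n_individuals=int(sum(counts)),
            )
        )
    return fitted


def _summary_from_fit(
    fit: _FittedSubcommunity, weights: np.ndarray, q: float, grid: GridSpec
) -> SubcommunitySummary:
    sd = hill_number(weights, q)
    mixture = weights @ fit.density_grids
    fd = functional_diversity_from_values(mixture, q, grid)
    return SubcommunitySummary(
        island=fit.island,
        zone=fit.zone,
        S=len(fit.species),
        n_individuals=fit.n_individuals,
        species_diversity_q2=sd,
        host_plants=fit.host_plants,
        normalized_diversity=sd / fit.host_plants,
        functional_diversity=fd,
    )


def subcommunity_summary(
    table: TraitTable,
    grid: GridSpec | None = None,
    density_method: str = "binormal_mle",
    q: float = 2.0,
    min_individuals: int = 3,
) -> list[SubcommunitySummary]:
    """Per-subcommunity species and functional diversity.

    Relative abundances come from sampled counts; species diversity is the
    Hill number of order ``q`` (inverse Simpson by default) normalized by the
    subcommunity's host-plant count, and functional diversity is computed
    from the abundance-weighted mixture of fitted species trait densities on
    a shared 101-bin [-1, 1]^2 grid.  Arid and humid zones are never pooled.
    """
    grid = grid or GridSpec(L=2)
    if grid.L != 2:
        raise ValueError("empirical trait space is 2-dimensional")
    fits = _fit_subcommunities(table, grid, density_method, min_individuals)
    return [
        _summary_from_fit(fit, fit.counts / fit.counts.sum(), q, grid)
        for fit in fits
    ]


def summaries_to_frame(summaries: list[SubcommunitySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


# ---------------------------------------------------------------------------
# regression and abundance randomization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of functional diversity on normalized species diversity."""

    slope: float
    slope_se: float
    p_value: float
    intercept: float
    n: int


def sd_fd_regression(summaries: list[SubcommunitySummary]) -> RegressionResult:
    """Ordinary least squares of functional diversity on normalized diversity.

    The p value is the two-sided t test on the slope, with no multiple-
    comparison correction.  Requires at least 3 subcommunities and a
    non-constant predictor.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 subcommunities for a regression")
    x = np.array([s.normalized_diversity for s in summaries])
    y = np.array([s.functional_diversity for s in summaries])
    if np.ptp(x) == 0:
        raise ValueError("predictor (normalized diversity) has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        intercept=float(res.params[0]),
        n=len(summaries),
    )


@dataclass(frozen=True)
class RandomizationResult:
    """Slope sample under randomized relative abundances."""

    fraction_negative: float
    slopes: np.ndarray


def abundance_randomization(
    table: TraitTable,
    trials: int,
    rng: np.random.Generator,
    grid: GridSpec | None = None,
    density_method: str = "binormal_mle",
    q: float = 2.0,
    min_individuals: int = 3,
    mode: str = "dirichlet",
    concentration: float = 1.0,
) -> RandomizationResult:
    """Sensitivity of the SD-FD slope to the recorded relative abundances.

    Per trial, each subcommunity's species weights are redrawn — uniformly on
    the simplex (symmetric Dirichlet, default concentration 1) or, with
    ``mode='multinomial'``, as multinomially resampled counts at the observed
    sampling depth — while trait distributions stay fixed; the regression
    slope is recomputed and the fraction of negative slopes returned.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if mode not in ("dirichlet", "multinomial"):
        raise ValueError("mode must be 'dirichlet' or 'multinomial'")
    grid = grid or GridSpec(L=2)
    fits = _fit_subcommunities(table, grid, density_method, min_individuals)
    if len(fits) < 3:
        raise ValueError("need at least 3 subcommunities for the randomization")
    slopes = np.empty(trials)
    for t in range(trials):
        xs, ys = [], []
        for fit in fits:
            S = len(fit.species)
            if mode == "dirichlet":
                w = rng.dirichlet(np.full(S, concentration))
            else:
                counts = rng.multinomial(int(fit.counts.sum()), np.full(S, 1.0 / S))
                while counts.sum() == 0:  # pragma: no cover - n>=min_individuals
                    counts = rng.multinomial(int(fit.counts.sum()), np.full(S, 1.0 / S))
                w = counts / counts.sum()
            w = np.clip(w, 1e-12, None)
            w = w / w.sum()
            summ = _summary_from_fit(fit, w, q, grid)
            xs.append(summ.normalized_diversity)
            ys.append(summ.functional_diversity)
        x, y = np.array(xs), np.array(ys)
        slopes[t] = np.polyfit(x, y, 1)[0] if np.ptp(x) > 0 else 0.0
    return RandomizationResult(
        fraction_negative=float((slopes < 0).mean()), slopes=slopes
    )


# ---------------------------------------------------------------------------
# synthetic fixture generator
# ---------------------------------------------------------------------------


def generate_fixture(
    n_subcommunities: int = 10,
    species_per_subcommunity: int | list[int] = 8,
    n_per_species: int = 50,
    sd_fd_slope_sign: int = -1,
    rng: np.random.Generator | None = None,
    host_plant_count: int = 5,
    sampling_jitter: float = 0.5,
) -> tuple[TraitTable, dict]:
    """Synthetic trait table emulating the island-snail data structure.

    Builds isolated subcommunities of binormal species clusters in a 2-D
    trait plane with unequal per-species sampling intensities.  Species
    richness rises across subcommunities while within-species trait spread
    either shrinks steeply with richness (``sd_fd_slope_sign < 0``, the
    trait-narrowing regime, giving a negative SD-FD relationship) or stays
    fixed (``sd_fd_slope_sign > 0``, giving the naive positive relationship).
    Sampling intensity varies by up to ``sampling_jitter`` (fractional) around
    ``n_per_species`` per species, emulating unequal sampling effort; set it
    to 0 for exactly ``n_per_species`` records per species.  Returns the
    table plus a ground-truth dictionary of the generating means,
    covariances, and per-species sample sizes for recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_subcommunities < 1 or n_per_species < 1:
        raise ValueError("sizes must be positive")
    if sd_fd_slope_sign == 0:
        raise ValueError("sd_fd_slope_sign must be nonzero")
    if isinstance(species_per_subcommunity, int):
        if species_per_subcommunity < 2:
            raise ValueError("species_per_subcommunity must be >= 2")
        counts = np.round(
            np.linspace(2, species_per_subcommunity, n_subcommunities)
        ).astype(int)
    else:
        counts = np.asarray(species_per_subcommunity, dtype=int)
        if counts.shape != (n_subcommunities,):
            raise ValueError("species_per_subcommunity list must have one entry per subcommunity")

    rows = []
    host_plants: dict[tuple[str, str], int] = {}
    truth: dict[tuple[str, str], dict] = {}
    for k in range(n_subcommunities):
        island = f"I{k + 1:02d}"
        zone = ZONES[k % 2]
        S = int(counts[k])
        if sd_fd_slope_sign < 0:
            sigma = 0.4 / S**2  # steep trait narrowing with richness
        else:
            sigma = 0.06  # fixed breadth: coverage grows with richness
        mu1 = np.linspace(-0.75, 0.75, S) if S > 1 else np.array([0.0])
        truth_sp = {}
        for s in range(S):
            name = f"sp_{island}_{s + 1:02d}"
            mean = np.array([mu1[s], rng.uniform(-0.2, 0.2)])
            cov = np.diag([sigma**2, (0.8 * sigma) ** 2])
            if sampling_jitter > 0:
                lo_n = max(3, int(round((1 - sampling_jitter) * n_per_species)))
                hi_n = int(round((1 + sampling_jitter) * n_per_species))
                n_s = int(rng.integers(lo_n, hi_n + 1))
            else:
                n_s = n_per_species
            draws = rng.multivariate_normal(mean, cov, size=n_s)
            for d in draws:
                rows.append(
                    {
                        "species": name,
                        "island": island,
                        "zone": zone,
                        "size": d[0],
                        "shapePC1": d[1],
                    }
                )
            truth_sp[name] = {"mean": mean, "cov": cov, "n": n_s}
        host_plants[(island, zone)] = host_plant_count
        truth[(island, zone)] = {
            "species": truth_sp,
            "host_plants": host_plant_count,
            "sigma": sigma,
        }
    table = TraitTable(data=pd.DataFrame(rows), host_plants=host_plants)
    return table, truth
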