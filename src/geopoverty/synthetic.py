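"""Synthetic landscapes and survey panels with known ground truth.

Two generators make every downstream stage testable without the global
raster and survey archives:

* :func:`generate_landscape` builds a full aligned layer stack — spatially
  autocorrelated NPP-trend field, agricultural extent, seeded market
  cities with an urban footprint, log-normal population surfaces for two
  epochs, a cost-distance travel-time surface, and a nearest-seed country
  partition.
* :func:`generate_panel` draws cross-country poverty spells from the
  two-equation structural model (poverty equation and growth-index
  equation) with known coefficients and cross-equation error correlation,
  so estimator bias, coverage and test size/power can be measured.

Each generator derives an independent substream from the run seed, so
landscape and panel generation are separately reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .grids import GridLayer, LayerStack, REGION_CODES

__all__ = [
    "LandscapeConfig",
    "PanelConfig",
    "generate_field",
    "compute_travel_time",
    "generate_landscape",
    "generate_panel",
]

#: Table-3-calibrated share distributions: mean and SD (percent of rural
#: population) for d1 (all DAL), d2 (remote DAL), i1 (all IAL), i2 (remote IAL).
DEFAULT_SHARE_DISTRIBUTIONS = {
    "d1": (27.11, 21.04),
    "d2": (5.02, 4.43),
    "i1": (31.89, 21.05),
    "i2": (13.45, 18.83),
}

DAL_SHARES = ("d1", "d2")
IAL_SHARES = ("i1", "i2")


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator."""

    nrows: int = 64
    ncols: int = 64
    n_countries: int = 6
    n_cities_per_country: int = 2
    smoothing_scale: float = 4.0       # cells; autocorrelation length of the fields
    agri_fraction: float = 0.5         # fraction of cells that are agricultural
    degrading_fraction: float = 0.35   # fraction of agri cells with negative NPP change
    urban_pop_share: float = 0.3       # fraction of total population in urban cells
    pop_total: float = 1_000_000.0     # persons, epoch 2000
    travel_cost_range: tuple[float, float] = (0.25, 1.5)  # hours per cell
    pop_growth_2000_2010: float = 0.13
    seed: int = 0

    def validate(self) -> None:
        for name in ("agri_fraction", "degrading_fraction", "urban_pop_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nrows < 1 or self.ncols < 1 or self.n_countries < 1:
            raise ValueError("grid size and country count must be >= 1")
        if self.n_countries > self.nrows * self.ncols:
            raise ValueError("more countries than grid cells")
        lo, hi = self.travel_cost_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("travel costs must be positive with max >= min")
        if self.smoothing_scale <= 0:
            raise ValueError("smoothing_scale must be positive")


@dataclass
class PanelConfig:
    """Parameters of the structural survey-panel generator.

    The poverty equation is
    ``gamma_H = beta0 + beta1*(1 -/+ s/100)*g + theta_direct*s + Gamma'Z + eps``
    (minus for DAL shares, plus for IAL shares) and the growth-index
    equation is ``g = delta0 + delta1*gamma_mu + Lambda'W + nu``, with
    corr(eps, nu) = ``error_corr`` providing genuine endogeneity of ``g``.
    """

    n_countries: int = 83
    beta0: float = -1.0
    beta1: float = -2.15
    delta0: float = 0.5
    delta1: float = 0.54
    theta_direct: float = 0.0
    share_variable: str = "d1"
    lambda_coefs: tuple[float, ...] = (0.8, -0.5)    # growth-equation controls W
    gamma_coefs: tuple[float, ...] = (0.6, -0.4)     # poverty-equation controls Z
    error_sd_P: float = 6.0
    error_sd_G: float = 1.5
    error_corr: float = 0.5
    share_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SHARE_DISTRIBUTIONS)
    )
    mean_income_growth: float = 3.36   # %/yr, sample mean
    sd_income_growth: float = 3.52     # %/yr, sample SD
    spell_length_range: tuple[int, int] = (2, 11)    # years
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 < self.error_corr < 1.0:
            raise ValueError("error_corr must lie strictly inside (-1, 1)")
        if self.spell_length_range[0] < 1:
            raise ValueError("spell lengths must be >= 1 year")
        if self.share_variable not in DAL_SHARES + IAL_SHARES:
            raise ValueError(
                f"share_variable must be one of {DAL_SHARES + IAL_SHARES}, "
                f"got {self.share_variable!r}"
            )
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent, named substream of a run seed (stable across processes)."""
    import hashlib

    tag = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def generate_field(
    shape: tuple[int, int],
    smoothing_scale: float,
    seed: int | np.random.Generator = 0,
) -> GridLayer:
    """Zero-mean unit-variance spatially autocorrelated Gaussian field.

    White noise is smoothed with a Gaussian kernel of the given scale
    (in cells) and re-standardised. Deterministic given the seed.
    """
    if smoothing_scale <= 0:
        raise ValueError("smoothing_scale must be positive")
    if shape[0] < 1 or shape[1] < 1:
        raise ValueError("shape must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=smoothing_scale, mode="wrap")
    f = (f - f.mean()) / f.std()
    return GridLayer(f, kind="npp_trend")


def compute_travel_time(
    cost: GridLayer, cities: Sequence[tuple[int, int]]
) -> GridLayer:
    """Minimal cumulative travel time (hours) from each cell to any market city.

    Moves go to the 8 neighbours; the step cost is the mean of the two
    cells' per-cell traversal costs, multiplied by sqrt(2) for diagonal
    moves. City cells get 0; cells cut off by nodata barriers get +inf.
    """
    if len(cities) == 0:
        raise ValueError("at least one market city is required")
    vals = cost.values
    valid = cost.valid_mask()
    if (vals[valid] <= 0).any():
        raise ValueError("all traversal costs must be positive")
    nrows, ncols = vals.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)

    rows_i, cols_i, weights = [], [], []
    moves = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    for dr, dc, mult in moves:
        r0, r1 = max(0, -dr), min(nrows, nrows - dr)
        c0, c1 = max(0, -dc), min(ncols, ncols - dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        va = valid[r0:r1, c0:c1] & valid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        w = 0.5 * (vals[r0:r1, c0:c1] + vals[r0 + dr : r1 + dr, c0 + dc : c1 + dc]) * mult
        rows_i.append(a[va])
        cols_i.append(b[va])
        weights.append(w[va])
    n = nrows * ncols
    graph = sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n, n),
    )
    sources = [idx[r, c] for r, c in cities]
    dist = dijkstra(graph, directed=False, indices=sources)
    best = dist.min(axis=0).reshape(nrows, ncols)
    best[~valid] = cost.nodata
    return GridLayer(
        best, kind="travel_time", cell_size=cost.cell_size, origin=cost.origin,
        nodata=cost.nodata,
    )


def _place_cities(
    potential: np.ndarray, zones: np.ndarray, n_countries: int, per_country: int,
    min_sep: float = 3.0,
) -> list[tuple[int, int]]:
    """Greedy top-potential city placement per country with a minimum spacing."""
    cities: list[tuple[int, int]] = []
    for z in range(1, n_countries + 1):
        cells = np.argwhere(zones == z)
        order = np.argsort(potential[cells[:, 0], cells[:, 1]])[::-1]
        placed: list[tuple[int, int]] = []
        for k in order:
            r, c = cells[k]
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed):
                placed.append((int(r), int(c)))
            if len(placed) >= per_country:
                break
        cities.extend(placed)
    return cities


def generate_landscape(config: LandscapeConfig) -> LayerStack:
    """Build an aligned synthetic layer stack under the given configuration."""
    config.validate()
    shape = (config.nrows, config.ncols)
    rng = _rng(config.seed, "landscape")

    # country partition: nearest of n random seed cells
    n_cells = config.nrows * config.ncols
    seeds = rng.choice(n_cells, size=config.n_countries, replace=False)
    seed_rc = np.column_stack(np.unravel_index(seeds, shape))
    rr, cc = np.meshgrid(np.arange(config.nrows), np.arange(config.ncols), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    _, nearest = cKDTree(seed_rc).query(pts)
    zones = (nearest + 1).reshape(shape).astype(float)

    # agricultural extent: threshold a smoothed field at the target quantile
    f_agri = generate_field(shape, config.smoothing_scale, rng).values
    if config.agri_fraction >= 1.0:
        agri = np.ones(shape)
    elif config.agri_fraction <= 0.0:
        agri = np.zeros(shape)
    else:
        thr = np.quantile(f_agri, 1.0 - config.agri_fraction)
        agri = (f_agri > thr).astype(float)

    # NPP trend: smoothed field shifted so that the requested fraction of
    # agricultural cells falls below zero
    f_npp = generate_field(shape, config.smoothing_scale, rng).values
    agri_vals = f_npp[agri == 1]
    if agri_vals.size:
        shift = np.quantile(agri_vals, config.degrading_fraction)
        if config.degrading_fraction <= 0.0:
            shift = agri_vals.min()  # exactly zero negatives after shifting
    else:
        shift = 0.0
    npp = (f_npp - shift) * 25.0  # scale to a gC/m2/yr-like magnitude

    # population potential and market cities
    f_pop = generate_field(shape, config.smoothing_scale, rng).values
    cities = _place_cities(f_pop, zones, config.n_countries, config.n_cities_per_country)
    city_rc = np.array(cities)
    d2city, _ = cKDTree(city_rc).query(pts)
    d2city = d2city.reshape(shape)

    # urban footprint: fixed 1.5-cell radius around each city
    urban = (d2city <= 1.5).astype(float)

    # log-normal population concentrated near cities, split so urban cells
    # hold urban_pop_share of the total
    w = np.exp(0.8 * f_pop - 0.15 * d2city)
    pop = np.zeros(shape)
    w_urb, w_rur = w[urban == 1], w[urban == 0]
    if w_urb.sum() > 0:
        pop[urban == 1] = w_urb / w_urb.sum() * config.urban_pop_share * config.pop_total
    if w_rur.sum() > 0:
        pop[urban == 0] = (
            w_rur / w_rur.sum() * (1.0 - config.urban_pop_share) * config.pop_total
        )

    noise = np.exp(rng.normal(0.0, 0.05, size=shape))
    pop_2010 = pop * (1.0 + config.pop_growth_2000_2010) * noise

    # travel-time surface from a smoothed positive cost field
    f_cost = generate_field(shape, config.smoothing_scale, rng).values
    lo, hi = config.travel_cost_range
    u = 1.0 / (1.0 + np.exp(-f_cost))  # logistic squash to (0, 1)
    cost = GridLayer(lo + (hi - lo) * u, kind="travel_time")
    travel = compute_travel_time(cost, cities)

    region_cycle = [c for c in REGION_CODES if c != "DEV"]
    region_map = {
        z: region_cycle[(z - 1) % len(region_cycle)] for z in range(1, config.n_countries + 1)
    }
    names = {z: f"Country-{z:03d}" for z in region_map}

    mk = lambda v, kind: GridLayer(np.asarray(v, dtype=float), kind=kind)
    return LayerStack(
        npp_trend=mk(npp, "npp_trend"),
        agri_mask=mk(agri, "mask"),
        urban_mask=mk(urban, "mask"),
        travel_time=travel,
        population_2000=mk(pop, "population"),
        population_2010=mk(pop_2010, "population"),
        country_zone=mk(zones, "zone"),
        region_map=region_map,
        country_names=names,
    )


def generate_panel(config: PanelConfig):
    """Draw a cross-country spell panel from the structural model.

    Returns ``(panel, truth)`` where ``panel`` is a pandas DataFrame with
    one row per country (spell endpoints, growth rates, shares, controls,
    the observed growth index ``g`` and instruments) and ``truth`` is a
    dict of the generating coefficients and error covariance.
    """
    import pandas as pd

    config.validate()
    rng = _rng(config.seed, "panel")
    n = config.n_countries

    shares = {}
    for name, (mu, sd) in config.share_distributions.items():
        shares[name] = np.clip(rng.normal(mu, sd, size=n), 0.0, 100.0)
    s = shares[config.share_variable]
    sign = -1.0 if config.share_variable in DAL_SHARES else 1.0

    gamma_mu = rng.normal(config.mean_income_growth, config.sd_income_growth, size=n)
    W = rng.standard_normal((n, len(config.lambda_coefs)))
    Z = rng.standard_normal((n, len(config.gamma_coefs)))

    cov = np.array(
        [
            [config.error_sd_P**2, config.error_corr * config.error_sd_P * config.error_sd_G],
            [config.error_corr * config.error_sd_P * config.error_sd_G, config.error_sd_G**2],
        ]
    )
    if config.error_sd_P == 0 and config.error_sd_G == 0:
        eps = nu = np.zeros(n)
    else:
        draws = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
        eps, nu = draws[:, 0], draws[:, 1]

    g = config.delta0 + config.delta1 * gamma_mu + W @ np.asarray(config.lambda_coefs) + nu
    adj = (1.0 + sign * s / 100.0) * g
    gamma_H = (
        config.beta0
        + config.beta1 * adj
        + config.theta_direct * s
        + Z @ np.asarray(config.gamma_coefs)
        + eps
    )

    # raw spell fields consistent with the generated growth rates
    lo, hi = config.spell_length_range
    spell_years = rng.integers(lo, hi + 1, size=n)
    t0 = np.full(n, 2000)
    t1 = t0 + spell_years
    H0 = rng.uniform(5.0, 95.0, size=n)
    H1 = H0 * np.exp(spell_years * gamma_H / 100.0)
    mu0 = np.exp(rng.normal(np.log(100.0), 0.8, size=n))
    mu1 = mu0 * np.exp(spell_years * gamma_mu / 100.0)
    welfare = rng.choice(["consumption", "income"], size=n, p=[0.7, 0.3])

    panel = pd.DataFrame(
        {
            "country": [f"C{i:03d}" for i in range(1, n + 1)],
            "t0": t0,
            "t1": t1,
            "welfare_type": welfare,
            "H0": H0,
            "H1": H1,
            "mu0": mu0,
            "mu1": mu1,
            "gamma_H": gamma_H,
            "gamma_mu": gamma_mu,
            **shares,
            "g": g,
            **{f"W{k+1}": W[:, k] for k in range(W.shape[1])},
            **{f"Z{k+1}": Z[:, k] for k in range(Z.shape[1])},
        }
    )
    truth = {
        "beta0": config.beta0,
        "beta1": config.beta1,
        "delta0": config.delta0,
        "delta1": config.delta1,
        "theta_direct": config.theta_direct,
        "lambda_coefs": list(config.lambda_coefs),
        "gamma_coefs": list(config.gamma_coefs),
        "share_variable": config.share_variable,
        "polarity": "dal" if sign < 0 else "ial",
        "error_cov": cov.tolist(),
        "instruments": [f"W{k+1}" for k in range(W.shape[1])],
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "share_distributions"},
    }
    return panel, truth
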