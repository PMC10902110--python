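"""Synthetic urban landscapes, pond networks and odonate communities.

The generator emulates the statistical structure the connectivity
analysis assumes: an urban mosaic raster (contiguous wetland clusters
embedded in a settlement/road matrix), stormwater and natural pond
sites, a literature-style flight-distance table, and site x species
count communities in which dragonfly abundance and richness increase
with connectivity, damselfly responses are null to weakly negative,
and a single indicator dragonfly is concentrated at high-connectivity
natural ponds. Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import CLASS_CODES, LAND_COVER_CLASSES, Raster
from .resistance import ResistanceRaster
from .stats import CommunityMatrix

__all__ = [
    "LandscapeConfig",
    "CommunityConfig",
    "INDICATOR_SPECIES",
    "default_class_mixture",
    "mixture_from_resistance_ratio",
    "generate_landscape",
    "generate_sites",
    "generate_community",
    "generate_site_metrics",
    "reference_flight_table",
    "two_corridor_resistance",
]

INDICATOR_SPECIES = "anisoptera_indicator"

#: Within-tier weights used when a mixture is built from a low/medium/high
#: resistance ratio. Chosen to resemble a temperate urban mosaic: open
#: water is rarer than wetland, settlement dominates the built tier.
_TIER_WEIGHTS = {
    "wetlands": 0.70,
    "water": 0.30,
    "crop_pasture": 0.29,
    "grassland": 0.23,
    "large_rivers": 0.02,
    "rock_barren": 0.03,
    "sand_gravel": 0.06,
    "wooded_area": 0.37,
    "settlement": 0.78,
    "transportation": 0.22,
}

_LOW = ("wetlands", "water")
_MEDIUM = ("crop_pasture", "grassland", "large_rivers", "rock_barren", "sand_gravel", "wooded_area")
_HIGH = ("settlement", "transportation")


def mixture_from_resistance_ratio(low: float, medium: float, high: float) -> dict[str, float]:
    """Per-class mixture realising a given low/medium/high resistance ratio."""
    total = low + medium + high
    if abs(total - 1.0) > 1e-9:
        raise ValueError("ratio must sum to 1")
    mix = {}
    for tier, classes in ((low, _LOW), (medium, _MEDIUM), (high, _HIGH)):
        wsum = sum(_TIER_WEIGHTS[c] for c in classes)
        for c in classes:
            mix[c] = tier * _TIER_WEIGHTS[c] / wsum
    return mix


def default_class_mixture() -> dict[str, float]:
    """Mixture reproducing the 14.2% / 34.8% / 51.0% low/medium/high ratio."""
    return mixture_from_resistance_ratio(0.142, 0.348, 0.510)


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic land-cover raster."""

    grid_rows: int = 200
    grid_cols: int = 200
    cell_size: float = 10.0
    class_mixture: dict[str, float] = field(default_factory=default_class_mixture)
    wetland_cluster_count: int = 5
    road_density: float | None = None  # None: take the mixture's transportation share
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.grid_rows < 3 or self.grid_cols < 3:
            raise ValueError("grid dimensions must be >= 3")
        unknown = set(self.class_mixture) - set(LAND_COVER_CLASSES)
        if unknown:
            raise ValueError(f"unknown land-cover classes: {sorted(unknown)}")
        props = np.array(list(self.class_mixture.values()), dtype=float)
        if (props < 0).any() or (props > 1).any():
            raise ValueError("class proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.wetland_cluster_count < 0:
            raise ValueError("wetland_cluster_count must be >= 0")


@dataclass
class CommunityConfig:
    """Parameters of the synthetic odonate community generator.

    Slopes are per standard deviation of connectivity on the log-mean
    count scale; ``dispersion`` is the negative-binomial size parameter
    (variance = mu + mu^2/dispersion; Poisson in the large limit).
    """

    n_sites: int = 49
    n_dragonfly_species: int = 9
    n_damselfly_species: int = 6
    dragonfly_abundance_slope: float = 1.0
    damselfly_richness_slope: float = -0.2
    indicator_species_slope: float = 1.5
    indicator_natural_bonus: float | None = None  # None: equal to indicator_species_slope
    dispersion: float = 2.0
    visit_aggregation: str = "sum"  # how the two seasonal visits combine
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("n_sites must be >= 4")
        if self.n_dragonfly_species < 1 or self.n_damselfly_species < 1:
            raise ValueError("need at least one species per suborder")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.visit_aggregation not in ("sum", "max"):
            raise ValueError("visit_aggregation must be 'sum' or 'max'")


# ----------------------------------------------------------- landscape


def _integer_targets(n: int, mixture: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n cells to classes."""
    names = list(mixture)
    raw = np.array([mixture[c] * n for c in names])
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:short]:
        base[i] += 1
    return dict(zip(names, base.tolist()))


def _draw_road(grid: np.ndarray, rng: np.random.Generator, remaining: int) -> int:
    """Carve one random 1-cell-wide polyline; returns cells newly converted."""
    nrows, ncols = grid.shape
    code = CLASS_CODES["transportation"]
    kind = rng.integers(4)
    if kind == 0:  # horizontal
        r = int(rng.integers(nrows))
        cells = [(r, c) for c in range(ncols)]
    elif kind == 1:  # vertical
        c = int(rng.integers(ncols))
        cells = [(r, c) for r in range(nrows)]
    else:  # diagonal, either direction
        offset = int(rng.integers(-nrows + 1, ncols))
        sign = 1 if kind == 2 else -1
        cells = []
        for r in range(nrows):
            c = offset + sign * r
            if 0 <= c < ncols:
                cells.append((r, c))
        if not cells:
            return 0
    placed = 0
    for r, c in cells:
        if grid[r, c] != code:
            grid[r, c] = code
            placed += 1
            if placed >= remaining:
                break
    return placed


def _grow_wetlands(
    grid: np.ndarray, rng: np.random.Generator, target: int, n_clusters: int
) -> None:
    """Seeded region growing of contiguous wetland clusters."""
    nrows, ncols = grid.shape
    code = CLASS_CODES["wetlands"]
    road = CLASS_CODES["transportation"]
    if target <= 0:
        return
    if n_clusters <= 0:
        # no clustering requested: scatter
        free = np.flatnonzero((grid != road).ravel())
        pick = rng.choice(free, size=min(target, free.size), replace=False)
        grid.ravel()[pick] = code
        return
    placed = 0
    frontier: list[tuple[int, int]] = []
    free = np.flatnonzero((grid.ravel() != road) & (grid.ravel() != code))
    kernels = rng.choice(free, size=min(n_clusters, free.size), replace=False)
    for k in kernels:
        frontier.append((k // ncols, k % ncols))
    while placed < target and frontier:
        i = int(rng.integers(len(frontier)))
        r, c = frontier.pop(i)
        if grid[r, c] == code or grid[r, c] == road:
            continue
        grid[r, c] = code
        placed += 1
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr or dc) and 0 <= rr < nrows and 0 <= cc < ncols:
                    if grid[rr, cc] != code and grid[rr, cc] != road:
                        frontier.append((rr, cc))
    if placed < target:  # landlocked by roads; top up anywhere free
        free = np.flatnonzero((grid.ravel() != road) & (grid.ravel() != code))
        extra = rng.choice(free, size=min(target - placed, free.size), replace=False)
        grid.ravel()[extra] = code


def generate_landscape(config: LandscapeConfig) -> Raster:
    """Generate a categorical land-cover raster matching the class mixture.

    Roads are drawn as random straight polylines, wetlands grown as
    contiguous clusters, and the remaining cells apportioned exactly to
    the other classes, so empirical proportions track the mixture
    closely on grids of 100 x 100 and up.
    """
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.grid_rows, config.grid_cols
    n = nrows * ncols
    targets = _integer_targets(n, config.class_mixture)

    grid = np.zeros((nrows, ncols), dtype=np.int16)  # 0 = unassigned
    road_target = targets.get("transportation", 0)
    if config.road_density is not None:
        road_target = int(round(config.road_density * n))
    remaining = road_target
    while remaining > 0:
        remaining -= _draw_road(grid, rng, remaining)

    _grow_wetlands(grid, rng, targets.get("wetlands", 0), config.wetland_cluster_count)

    # apportion the remaining cells exactly among the other classes
    others = {
        c: t for c, t in targets.items() if c not in ("transportation", "wetlands") and t > 0
    }
    free = np.flatnonzero(grid.ravel() == 0)
    if others:
        share = {c: t / sum(others.values()) for c, t in others.items()}
        counts = _integer_targets(free.size, share)
        rng.shuffle(free)
        start = 0
        for cls, cnt in counts.items():
            grid.ravel()[free[start : start + cnt]] = CLASS_CODES[cls]
            start += cnt
    elif free.size:
        # degenerate mixtures (e.g. pure wetlands): backfill with the
        # dominant structured class
        backfill = "wetlands" if targets.get("wetlands", 0) else "transportation"
        grid.ravel()[free] = CLASS_CODES[backfill]

    return Raster(
        grid,
        cell_size=config.cell_size,
        metadata={"seed": config.seed, "mixture": dict(config.class_mixture)},
    )


# --------------------------------------------------------------- sites


def generate_sites(
    raster: Raster, n_stormwater: int = 41, n_natural: int = 8, seed: int | None = None
) -> pd.DataFrame:
    """Place stormwater and natural pond sites on a land-cover raster.

    Natural ponds sit inside or adjacent to wetland clusters; stormwater
    ponds in settlement-dominated neighbourhoods (highest built fraction
    in a 7 x 7 window). Returns a table with columns id, x, y, type.
    """
    if n_stormwater < 0 or n_natural < 0:
        raise ValueError("site counts must be >= 0")
    rng = np.random.default_rng(seed)
    grid = raster.values
    wet = grid == CLASS_CODES["wetlands"]
    near_wet = ndimage.binary_dilation(wet, structure=np.ones((3, 3), bool))
    natural_candidates = np.flatnonzero(near_wet.ravel())
    if len(natural_candidates) < n_natural:
        raise ValueError(
            f"insufficient wetland-adjacent cells for natural ponds: "
            f"need {n_natural}, have {len(natural_candidates)}"
        )
    natural_pick = (
        rng.choice(natural_candidates, size=n_natural, replace=False) if n_natural else np.array([], int)
    )

    settle = (grid == CLASS_CODES["settlement"]).astype(float)
    frac = ndimage.uniform_filter(settle, size=7, mode="constant")
    storm_mask = (frac >= 0.25) & ~near_wet
    storm_candidates = np.setdiff1d(np.flatnonzero(storm_mask.ravel()), natural_pick)
    if len(storm_candidates) < n_stormwater:
        raise ValueError(
            f"insufficient settlement-dominated cells (>=25% built within 7x7 window) "
            f"for stormwater ponds: need {n_stormwater}, have {len(storm_candidates)}"
        )
    storm_pick = (
        rng.choice(storm_candidates, size=n_stormwater, replace=False)
        if n_stormwater
        else np.array([], int)
    )

    ncols = grid.shape[1]
    rows = []
    for i, flat in enumerate(sorted(storm_pick.tolist())):
        x, y = raster.cell_center(flat // ncols, flat % ncols)
        rows.append({"id": f"SW{i + 1:02d}", "x": x, "y": y, "type": "stormwater"})
    for i, flat in enumerate(sorted(natural_pick.tolist())):
        x, y = raster.cell_center(flat // ncols, flat % ncols)
        rows.append({"id": f"NP{i + 1:02d}", "x": x, "y": y, "type": "natural"})
    return pd.DataFrame(rows, columns=["id", "x", "y", "type"])


# ----------------------------------------------------------- community


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion > 1e6:  # Poisson limit
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def generate_community(
    metrics, config: CommunityConfig, return_visits: bool = False
):
    """Draw an odonate community responding to standardised connectivity.

    ``metrics`` is a per-site connectivity vector, or a DataFrame with a
    ``mean_current`` column (one row per site; filter to one scale
    first). Connectivity is z-scored across sites; each species' counts
    are negative binomial with log-mean linear in z. Dragonflies use
    ``dragonfly_abundance_slope``; the single indicator species uses
    ``indicator_species_slope`` and, when a ``type`` column is present,
    an extra log-mean bonus at natural ponds (defaulting to the
    indicator slope, so an all-zero-slope configuration is a true
    null); damselflies use ``damselfly_richness_slope``. Counts are
    drawn per seasonal visit (two visits) and aggregated by the
    configured rule.
    """
    site_ids = None
    site_type = None
    if isinstance(metrics, pd.DataFrame):
        if "scale_m" in metrics.columns and metrics["scale_m"].nunique() > 1:
            raise ValueError("metrics table mixes scales; filter to a single scale_m first")
        conn = metrics["mean_current"].to_numpy(dtype=float)
        if "pond_id" in metrics.columns:
            site_ids = metrics["pond_id"].tolist()
        elif "id" in metrics.columns:
            site_ids = metrics["id"].tolist()
        if "type" in metrics.columns:
            site_type = metrics["type"].to_numpy()
    else:
        conn = np.asarray(metrics, dtype=float)
    if not np.all(np.isfinite(conn)):
        raise ValueError("connectivity contains non-finite values")
    if len(conn) != config.n_sites:
        raise ValueError(f"config.n_sites={config.n_sites} but metrics has {len(conn)} sites")
    sd = conn.std()
    z = (conn - conn.mean()) / sd if sd > 0 else np.zeros_like(conn)

    rng = np.random.default_rng(config.seed)
    species = [INDICATOR_SPECIES] + [
        f"anisoptera_sp{i:02d}" for i in range(2, config.n_dragonfly_species + 1)
    ] + [f"zygoptera_sp{i:02d}" for i in range(1, config.n_damselfly_species + 1)]
    suborder = pd.Series(
        ["Anisoptera"] * config.n_dragonfly_species + ["Zygoptera"] * config.n_damselfly_species,
        index=species,
        name="suborder",
    )

    intercepts = rng.normal(np.log(4.0), 0.5, size=len(species))
    intercepts[0] = np.log(2.0)  # indicator is rarer overall
    slopes = np.concatenate(
        [
            [config.indicator_species_slope],
            np.full(config.n_dragonfly_species - 1, config.dragonfly_abundance_slope),
            np.full(config.n_damselfly_species, config.damselfly_richness_slope),
        ]
    )
    log_mu = intercepts[None, :] + np.outer(z, slopes)
    bonus = (
        config.indicator_natural_bonus
        if config.indicator_natural_bonus is not None
        else config.indicator_species_slope
    )
    if site_type is not None and bonus:
        log_mu[:, 0] += np.where(site_type == "natural", bonus, 0.0)
    mu = np.exp(log_mu)

    visits = np.stack([_nb_draw(rng, mu / 2.0, config.dispersion) for _ in range(2)])
    counts = visits.sum(axis=0) if config.visit_aggregation == "sum" else visits.max(axis=0)

    index = site_ids if site_ids is not None else [f"site{i + 1:03d}" for i in range(len(conn))]
    cm = CommunityMatrix(pd.DataFrame(counts, index=index, columns=species), suborder)
    if return_visits:
        return cm, visits
    return cm


def generate_site_metrics(
    n_sites: int = 49, n_natural: int | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plausible site table + two-scale metrics table without a landscape run.

    Natural ponds draw higher (log10) mean current and more neighbours
    than stormwater ponds, with neighbour counts positively correlated
    with current — the empirical regime the analysis operates in. Useful
    for statistical simulation studies where the raster stage is not the
    object under test. Returns (sites, metrics).
    """
    rng = np.random.default_rng(seed)
    if n_natural is None:
        n_natural = max(1, round(n_sites * 8 / 49))
    n_storm = n_sites - n_natural
    types = np.array(["stormwater"] * n_storm + ["natural"] * n_natural)
    ids = [f"SW{i + 1:02d}" for i in range(n_storm)] + [f"NP{i + 1:02d}" for i in range(n_natural)]
    sites = pd.DataFrame(
        {
            "id": ids,
            "x": rng.uniform(0, 20000, n_sites),
            "y": rng.uniform(0, 20000, n_sites),
            "type": types,
        }
    )
    rows = []
    params = {  # per scale: (storm mean, natural mean, sd, storm nb, natural nb)
        900.0: (-0.69, -0.20, 0.15, 11.0, 94.0),
        300.0: (-0.70, -0.24, 0.18, 2.0, 11.0),
    }
    for scale, (mu_s, mu_n, sd_c, nb_s, nb_n) in params.items():
        mu = np.where(types == "natural", mu_n, mu_s)
        current = rng.normal(mu, sd_c)
        nb_mu = np.where(types == "natural", nb_n, nb_s) * np.exp(1.2 * (current - mu))
        n_nb = rng.poisson(nb_mu)
        for i in range(n_sites):
            rows.append(
                {
                    "pond_id": ids[i],
                    "scale_m": scale,
                    "mean_current": current[i],
                    "sd_current": abs(rng.normal(0.30, 0.05)),
                    "n_neighbours": int(n_nb[i]),
                    "type": types[i],
                }
            )
    return sites, pd.DataFrame(rows)


# -------------------------------------------------- flight distances


def reference_flight_table() -> pd.DataFrame:
    """Synthetic literature table of daily odonate flight distances.

    Mimics the structure of a systematic-review extraction: species,
    suborder, mean and (optional) maximum tracked daily distance in
    metres. The suborder maxima of the mean distances round to 900 m
    (Anisoptera) and 300 m (Zygoptera), the scales used for analysis.
    """
    rows = [
        ("anisoptera_hawker_a", "Anisoptera", 889.0, 3100.0),
        ("anisoptera_hawker_b", "Anisoptera", 612.0, 1800.0),
        ("anisoptera_darter_a", "Anisoptera", 486.0, 1150.0),
        ("anisoptera_darter_b", "Anisoptera", 320.0, 900.0),
        ("anisoptera_skimmer_a", "Anisoptera", 257.0, 640.0),
        ("anisoptera_skimmer_b", "Anisoptera", 184.0, np.nan),
        ("anisoptera_whiteface_a", "Anisoptera", 118.0, 410.0),
        ("zygoptera_spreadwing_a", "Zygoptera", 316.0, 820.0),
        ("zygoptera_damsel_a", "Zygoptera", 204.0, 560.0),
        ("zygoptera_damsel_b", "Zygoptera", 147.0, np.nan),
        ("zygoptera_damsel_c", "Zygoptera", 88.0, 230.0),
        ("zygoptera_damsel_d", "Zygoptera", 41.0, 120.0),
    ]
    return pd.DataFrame(
        rows, columns=["species", "suborder", "mean_daily_distance_m", "max_daily_distance_m"]
    )


# ------------------------------------------------------ toy landscapes


def two_corridor_resistance(
    corridor_a: float = 10.0, corridor_b: float = 10.0, size: int = 21
) -> tuple[ResistanceRaster, int, int]:
    """Toy landscape with two movement corridors between two low-cost buses.

    A high-resistance (100) matrix crossed by two horizontal corridors
    (rows size//4 and 3*size//4) joining low-resistance vertical strips
    on the left and right edges. Returns the resistance raster and the
    flat indices of mid-left and mid-right terminal cells — useful for
    showing that current reroutes when one corridor degrades.
    """
    grid = np.full((size, size), 100.0)
    ra, rb = size // 4, (3 * size) // 4
    grid[ra, :] = corridor_a
    grid[rb, :] = corridor_b
    grid[:, 0] = 1.0
    grid[:, -1] = 1.0
    rr = ResistanceRaster(Raster(grid, cell_size=10.0), np.ones_like(grid, dtype=bool))
    mid = size // 2
    return rr, mid * size + 0, mid * size + (size - 1)
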