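"""Synthetic two-slope species-range data with the statistical structure the
analyses assume.

The generator emulates the study design: two slopes of a single massif split
into 250-m elevational bands (southern slope 1250-3650 m, 10 bands; northern
slope 1000-3700 m, 11 bands), 29 and 18 rodent species with contiguous
elevational ranges (17 shared between slopes), Oriental/Palaearctic realm
labels whose Oriental fraction declines with elevation, per-band covariates
(AMT from the slope-specific lapse models, declining AMP and EVI, hump-shaped
band area), and optional site-level detections within bands.

Scenarios control the richness shape:

* ``mde_null``       - ranges placed uniformly between the hard boundaries,
* ``monotonic_decline`` - range low ends biased toward the base,
* ``hump``           - range midpoints biased toward the domain centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as edio
from .core import ElevationGrid, SpeciesRange, build_grid, build_incidence
from .covariates import NORTH_LAPSE, SOUTH_LAPSE, LapseModel, amt_at

SCENARIOS = ("mde_null", "monotonic_decline", "hump", "custom")
SIZE_DISTRIBUTIONS = ("uniform", "empirical_pool", "truncated_geometric")


def default_grids() -> dict[str, ElevationGrid]:
    return {
        "south": build_grid("south", 1250, 3650, 250),
        "north": build_grid("north", 1000, 3700, 250),
    }


DEFAULT_LAPSE = {"south": SOUTH_LAPSE, "north": NORTH_LAPSE}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the field survey: 29 southern and 18 northern species
    drawn from a 30-species pool with 17 shared; realm mixture ~60% Oriental
    overall with log-odds of Oriental declining by ``realm_elev_slope`` per
    standardised unit of range-midpoint elevation; 3 survey sites per band
    with per-site detection probability 0.7.
    """

    scenario: str = "mde_null"
    n_species: dict[str, int] = field(default_factory=lambda: {"south": 29, "north": 18})
    n_shared: int = 17
    range_size_distribution: str = "uniform"
    mean_range_bands: float = 4.0  # mean for truncated_geometric
    size_pool: tuple[int, ...] | None = None  # for empirical_pool
    p_oriental: float = 0.6
    realm_elev_slope: float = -1.5  # log-odds of Oriental per sd of midpoint elevation
    gap_probability: float = 0.2  # interior bands missing from the *observed* set
    detection_probability: float = 0.7
    sites_per_band: int = 3
    covariate_noise_sd: float = 0.05  # relative noise on AMP/EVI/area
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.range_size_distribution not in SIZE_DISTRIBUTIONS:
            raise ValueError(
                f"unknown range_size_distribution {self.range_size_distribution!r}"
            )
        for key in ("p_oriental", "gap_probability", "detection_probability"):
            v = getattr(self, key)
            if not (0 <= v <= 1):
                raise ValueError(f"{key} must be in [0, 1], got {v}")
        if any(n < 1 for n in self.n_species.values()) or self.sites_per_band < 1:
            raise ValueError("species and site counts must be >= 1")


def _species_pool(config: ScenarioConfig) -> dict[str, list[str]]:
    """Assign species ids to slopes with the configured overlap."""
    slopes = list(config.n_species)
    counts = config.n_species
    if len(slopes) == 1:
        s = slopes[0]
        return {s: [f"sp{i + 1:02d}" for i in range(counts[s])]}
    a, b = slopes[0], slopes[1]
    shared = min(config.n_shared, counts[a], counts[b])
    total = counts[a] + counts[b] - shared
    pool = [f"sp{i + 1:02d}" for i in range(total)]
    ids_a = pool[: counts[a]]
    # shared species are the last `shared` of slope a's list
    ids_b = ids_a[counts[a] - shared :] + pool[counts[a] :]
    return {a: ids_a, b: ids_b}


def _draw_size(rng: np.random.Generator, config: ScenarioConfig, n_bands: int) -> int:
    dist = config.range_size_distribution
    if dist == "uniform":
        return int(rng.integers(1, n_bands + 1))
    if dist == "empirical_pool":
        if not config.size_pool:
            raise ValueError("empirical_pool distribution needs a size_pool")
        pool = np.asarray(config.size_pool, dtype=int)
        if (pool < 1).any() or (pool > n_bands).any():
            raise ValueError("size_pool entries must lie within the domain")
        return int(rng.choice(pool))
    # truncated geometric on {1..n_bands} with the configured mean
    p = min(max(1.0 / max(config.mean_range_bands, 1.0), 1e-6), 1.0)
    for _ in range(1000):
        r = int(rng.geometric(p))
        if r <= n_bands:
            return r
    raise RuntimeError("could not draw a feasible range size in 1000 attempts")


def _draw_start(rng: np.random.Generator, config: ScenarioConfig, r: int, B: int) -> int:
    feasible = np.arange(B - r + 1)
    if config.scenario in ("mde_null", "custom"):
        return int(rng.choice(feasible))
    if config.scenario == "monotonic_decline":
        # low ends anchored near the base so richness declines with elevation;
        # a sub-band decay scale keeps the expected decline close to linear
        # (weak anchoring leaves convex curvature that mimics a mid-domain hump)
        w = np.exp(-feasible / 0.5)
    else:  # hump: range midpoints biased toward the domain centre
        mid = feasible + (r - 1) / 2.0
        w = np.exp(-((mid - (B - 1) / 2.0) ** 2) / (2 * (B / 6.0) ** 2))
    return int(rng.choice(feasible, p=w / w.sum()))


def generate_ranges(
    config: ScenarioConfig,
    grids: dict[str, ElevationGrid] | None = None,
) -> dict[str, list[SpeciesRange]]:
    """Per-slope species ranges under the configured scenario.

    The observed band set keeps the interval endpoints and drops interior
    bands independently with ``gap_probability``, so downstream range
    interpolation has gaps to fill.  Same seed, same tables.
    """
    grids = grids if grids is not None else default_grids()
    if set(config.n_species) - set(grids):
        raise ValueError("n_species names a slope with no grid")
    rng = np.random.default_rng(config.seed)
    pools = _species_pool(config)
    out: dict[str, list[SpeciesRange]] = {}
    for slope in config.n_species:
        grid = grids[slope]
        B = grid.n_bands
        mids = grid.midpoints
        mid_mu, mid_sd = mids.mean(), mids.std()
        ranges = []
        for sp in pools[slope]:
            r = _draw_size(rng, config, B)
            start = _draw_start(rng, config, r, B)
            low, high = start, start + r - 1
            observed = {low, high}
            for band in range(low + 1, high):
                if rng.random() >= config.gap_probability:
                    observed.add(band)
            mid_elev = (mids[low] + mids[high]) / 2.0
            z = (mid_elev - mid_mu) / mid_sd
            logit = np.log(config.p_oriental / (1 - config.p_oriental)) if 0 < config.p_oriental < 1 else (
                np.inf if config.p_oriental == 1 else -np.inf
            )
            p_or = 1.0 / (1.0 + np.exp(-(logit + config.realm_elev_slope * z)))
            realm = "Oriental" if rng.random() < p_or else "Palaearctic"
            ranges.append(SpeciesRange(sp, slope, frozenset(observed), realm))
        out[slope] = ranges
    return out


def generate_sites(
    ranges: dict[str, list[SpeciesRange]],
    config: ScenarioConfig,
    grids: dict[str, ElevationGrid] | None = None,
) -> pd.DataFrame:
    """Site-level detection table (site_id, slope, band_index, species_id).

    ``sites_per_band`` sites are placed in every band; each species present
    in the band (after interpolation) is detected independently at each site
    with ``detection_probability``.
    """
    grids = grids if grids is not None else default_grids()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for slope, slope_ranges in ranges.items():
        grid = grids[slope]
        inc = build_incidence(grid, slope_ranges)
        pres = inc.presence
        for band in range(grid.n_bands):
            present = [sp for sp in inc.species if pres.iloc[band][sp]]
            for s in range(config.sites_per_band):
                site_id = f"{slope}_b{band:02d}_s{s + 1}"
                for sp in present:
                    if rng.random() < config.detection_probability:
                        rows.append((site_id, slope, band, sp))
    return pd.DataFrame(rows, columns=["site_id", "slope", "band_index", "species_id"])


def generate_covariates(
    grids: dict[str, ElevationGrid] | None = None,
    config: ScenarioConfig = ScenarioConfig(),
    lapse_models: dict[str, LapseModel] | None = None,
    *,
    amp_monotone: bool = True,
    area_unimodal: bool = True,
) -> pd.DataFrame:
    """Per-band covariate table.

    AMT is the lapse model evaluated exactly at band midpoints.  AMP and EVI
    decline smoothly with elevation, band area is hump-shaped (one interior
    maximum), each with multiplicative noise of relative sd
    ``covariate_noise_sd`` (0 gives deterministic functions of elevation).
    """
    grids = grids if grids is not None else default_grids()
    lapse_models = lapse_models if lapse_models is not None else DEFAULT_LAPSE
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    frames = []
    for slope, grid in grids.items():
        if slope not in lapse_models:
            raise ValueError(f"no lapse model for slope {slope!r}")
        mids = grid.midpoints
        u = (mids - mids.min()) / (mids.max() - mids.min())  # 0..1 up the gradient
        noise = lambda size: 1.0 + config.covariate_noise_sd * rng.standard_normal(size)
        amp = (900.0 - (500.0 * u if amp_monotone else 200.0 * np.sin(np.pi * u))) * noise(len(u))
        evi = np.clip((0.55 - 0.35 * u) * noise(len(u)), -1.0, 1.0)
        if area_unimodal:
            area = (40.0 + 120.0 * np.exp(-((u - 0.5) ** 2) / (2 * 0.2**2))) * noise(len(u))
        else:
            area = (160.0 - 120.0 * u) * noise(len(u))
        frames.append(
            pd.DataFrame(
                {
                    "slope": slope,
                    "band_index": np.arange(grid.n_bands),
                    "band_mid_m": mids,
                    "amt_c": amt_at(mids, lapse_models[slope]),
                    "amp_mm": np.maximum(amp, 0.0),
                    "evi": evi,
                    "area_km2": np.maximum(area, 0.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_distance_matrix(grid: ElevationGrid) -> pd.DataFrame:
    """Band-to-band distance surrogate: separation of band midpoints (m).

    Stands in for the geographic distance matrix between survey sites when no
    coordinates are available.
    """
    mids = grid.midpoints
    d = np.abs(mids[:, None] - mids[None, :])
    labels = [f"band{i}" for i in range(grid.n_bands)]
    return pd.DataFrame(d, index=labels, columns=labels)


def write_scenario(config: ScenarioConfig, out_dir, grids: dict[str, ElevationGrid] | None = None) -> dict[str, Path]:
    """Generate one scenario and write ranges/sites/covariates/distances.

    Output is byte-reproducible for a given config (including seed).
    """
    grids = grids if grids is not None else default_grids()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ranges = generate_ranges(config, grids)
    paths = {"ranges": out_dir / "ranges.csv"}
    edio.write_ranges([r for rs in ranges.values() for r in rs], paths["ranges"], grids)
    sites = generate_sites(ranges, config, grids)
    paths["sites"] = out_dir / "sites.csv"
    sites.to_csv(paths["sites"], index=False)
    cov = generate_covariates(grids, config)
    paths["covariates"] = out_dir / "covariates.csv"
    edio.write_covariates(cov, paths["covariates"])
    for slope, grid in grids.items():
        key = f"dist_{slope}"
        paths[key] = out_dir / f"dist_{slope}.csv"
        edio.write_distance_matrix(generate_distance_matrix(grid), paths[key])
    return paths
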