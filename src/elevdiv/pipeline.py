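"""End-to-end orchestration: ingest ranges -> interpolate -> MDE null ->
multi-model inference -> beta diversity -> machine-readable report.

Every analysis is repeated per slope for three species groups: all species,
larger-ranged (above the median range size), and smaller-ranged, with the
median split recomputed within each slope by default.  Beta-diversity and
realm-composition analyses run on all species only.  All randomness derives
from a single master seed, so a rerun with the same inputs and seed writes a
byte-identical report.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as edio
from .beta import (
    adjacent_turnover,
    cross_slope_turnover,
    dissimilarity_matrix,
    mantel,
    turnover_elevation_fit,
    whittaker_from_incidence,
    whittaker_from_sites,
)
from .core import (
    ElevationGrid,
    SpeciesRange,
    build_grid,
    build_incidence,
    median_split,
    realm_richness,
    richness,
    shared_species,
)
from .covariates import pair_bands, paired_t_test
from .inference import all_subsets, polynomial_select
from .mde import MDEConfig, analytic_mde_expectation, fit_observed_vs_predicted, simulate_mde

GROUPS = ("all", "larger", "smaller")
PREDICTORS = ("mde", "amt", "amp", "evi", "area")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass(frozen=True)
class RunConfig:
    ranges_path: str
    covariates_path: str
    grids: dict[str, ElevationGrid]
    out_dir: str
    distance_paths: dict[str, str] = field(default_factory=dict)
    sites_path: str | None = None
    n_sims: int = 50_000
    n_perm: int = 1000
    seed: int = 0
    groups: tuple[str, ...] = GROUPS
    median_tie: str = "smaller"
    global_split: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        grids = {
            slope: build_grid(slope, g["min_elev"], g["max_elev"], g.get("band_width", 250))
            for slope, g in raw.pop("grids").items()
        }
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(grids=grids, **raw)


def _derived_seed(master: int, tag: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed and a tag."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else round(f, 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


@_stage("group_analysis")
def _analyse_group(
    slope: str,
    group: str,
    grp_ranges: Sequence[SpeciesRange],
    grid: ElevationGrid,
    cov: pd.DataFrame,
    config: RunConfig,
    out_dir: Path,
) -> dict:
    if len(grp_ranges) < 2:
        raise PipelineError(f"group {group!r} on slope {slope!r} has fewer than 2 species")
    inc = build_incidence(grid, list(grp_ranges))
    rich = richness(inc)
    sizes = inc.range_sizes_bands()

    mde_cfg = MDEConfig(n_sims=config.n_sims, seed=_derived_seed(config.seed, f"mde/{slope}/{group}"))
    mde_res = simulate_mde(sizes, grid, mde_cfg)
    mde_fit = fit_observed_vs_predicted(rich, mde_res.predicted_mean)
    poly = polynomial_select(rich, grid.midpoints)

    predictors = {
        "mde": mde_res.predicted_mean,
        "amt": cov["amt_c"].to_numpy(),
        "amp": cov["amp_mm"].to_numpy(),
        "evi": cov["evi"].to_numpy(),
        "area": cov["area_km2"].to_numpy(),
    }
    models = all_subsets(rich, predictors)

    tag = f"{slope}_{group}"
    pd.DataFrame(
        {
            "band_index": np.arange(grid.n_bands),
            "band_mid_m": grid.midpoints,
            "observed": rich.counts,
            "predicted_mean": mde_res.predicted_mean,
            "lower95": mde_res.lower95,
            "upper95": mde_res.upper95,
        }
    ).to_csv(out_dir / f"mde_{tag}.csv", index=False)
    pd.DataFrame(
        [
            {
                "subset": "+".join(f.predictor_subset),
                "k": f.k,
                "rss": f.rss,
                "aicc": f.aicc,
                "delta_aicc": d,
                "weight": w,
                "collinear": f.collinear,
            }
            for f, d, w in zip(models.fits, models.delta_aicc, models.weights)
        ]
    ).to_csv(out_dir / f"models_{tag}.csv", index=False)
    pd.DataFrame(
        {
            "predictor": list(PREDICTORS),
            "impact_factor": [models.impact_factors[p] for p in PREDICTORS],
            "important": [models.important[p] for p in PREDICTORS],
            "averaged_beta": [models.averaged_betas[p] for p in PREDICTORS],
            "averaged_se": [models.averaged_se[p] for p in PREDICTORS],
            "best_model_beta": [models.best.std_betas.get(p) for p in PREDICTORS],
        }
    ).to_csv(out_dir / f"inference_{tag}.csv", index=False)

    return {
        "n_species": len(grp_ranges),
        "richness": rich.counts,
        "mde": {
            "n_sims": mde_res.n_sims,
            "seed": mde_res.seed,
            "predicted_mean": mde_res.predicted_mean,
            "lower95": mde_res.lower95,
            "upper95": mde_res.upper95,
            "fit": {
                "r_squared": mde_fit.r_squared,
                "slope": mde_fit.slope,
                "intercept": mde_fit.intercept,
                "p_value": mde_fit.p_value,
            },
        },
        "polynomial": {
            "order": poly.order,
            "r_squared": poly.r_squared,
            "coefficients": poly.coefficients,
        },
        "models": {
            "n_models": len(models.fits),
            "best_subset": list(models.best.predictor_subset),
            "best_aicc": models.best.aicc,
            "weights_sum": float(models.weights.sum()),
            "impact_factors": models.impact_factors,
            "important": models.important,
            "averaged_betas": models.averaged_betas,
            "averaged_se": models.averaged_se,
        },
    }


@_stage("beta_diversity")
def _analyse_beta(
    slope: str,
    slope_ranges: Sequence[SpeciesRange],
    grid: ElevationGrid,
    config: RunConfig,
    sites: pd.DataFrame | None,
    out_dir: Path,
) -> dict:
    inc = build_incidence(grid, list(slope_ranges))
    turnover = adjacent_turnover(inc)
    boundaries = grid.band_starts[1:]  # elevation of each band boundary
    fit = None
    finite = np.isfinite(turnover)
    if finite.sum() >= 6 and np.ptp(turnover[finite]) > 0:
        pf = turnover_elevation_fit(turnover, boundaries)
        fit = {"order": pf.order, "r_squared": pf.r_squared, "coefficients": pf.coefficients}
    dmat = dissimilarity_matrix(inc)
    dmat.to_frame().to_csv(out_dir / f"sorensen_{slope}.csv")
    pd.DataFrame(
        {"boundary_elev_m": boundaries, "sorensen": turnover}
    ).to_csv(out_dir / f"turnover_{slope}.csv", index=False)

    mantel_res = None
    if slope in config.distance_paths:
        dist = edio.read_distance_matrix(config.distance_paths[slope])
        res = mantel(
            dmat.to_frame(),
            dist,
            n_perm=config.n_perm,
            seed=_derived_seed(config.seed, f"mantel/{slope}"),
        )
        mantel_res = {"r": res.r, "p": res.p, "n_perm": res.n_perm, "tail": res.tail}

    if sites is not None and not sites[sites["slope"] == slope].empty:
        whit = whittaker_from_sites(sites[sites["slope"] == slope])
        alpha_source = "sites"
    else:
        whit = whittaker_from_incidence(inc)
        alpha_source = "bands"
    return {
        "adjacent_turnover": turnover,
        "turnover_fit": fit,
        "mantel": mantel_res,
        "whittaker": {"value": whit, "alpha_source": alpha_source},
    }


def run_analysis(config: RunConfig) -> dict:
    """Run every stage for both slopes and all species groups; returns the
    report dict and writes CSV outputs plus report.json to the output dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        ranges = edio.read_ranges(config.ranges_path, config.grids)
        cov_all = edio.read_covariates(config.covariates_path)
        sites = pd.read_csv(config.sites_path) if config.sites_path else None
    except Exception as exc:
        raise PipelineError(f"stage 'ingest': {exc}") from exc

    by_slope: dict[str, list[SpeciesRange]] = {s: [] for s in config.grids}
    for r in ranges:
        by_slope[r.slope_label].append(r)

    # optional global split: median computed over all species pooled
    global_groups: dict[str, set[tuple[str, str]]] | None = None
    if config.global_split:
        larger, smaller = median_split(ranges, tie=config.median_tie)
        global_groups = {
            "larger": {(r.slope_label, r.species_id) for r in larger},
            "smaller": {(r.slope_label, r.species_id) for r in smaller},
        }

    report: dict[str, Any] = {
        "version": __version__,
        "config": {
            "ranges_path": str(config.ranges_path),
            "covariates_path": str(config.covariates_path),
            "sites_path": str(config.sites_path) if config.sites_path else None,
            "distance_paths": {k: str(v) for k, v in config.distance_paths.items()},
            "grids": {
                s: {"base": g.base_elevation, "band_width": g.band_width, "n_bands": g.n_bands}
                for s, g in config.grids.items()
            },
            "n_sims": config.n_sims,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "groups": list(config.groups),
            "median_tie": config.median_tie,
            "global_split": config.global_split,
        },
        "slopes": {},
    }

    for slope, grid in config.grids.items():
        slope_ranges = by_slope[slope]
        if not slope_ranges:
            raise PipelineError(f"stage 'ingest': no species ranges for slope {slope!r}")
        cov = cov_all[cov_all["slope"] == slope].sort_values("band_index")
        if len(cov) != grid.n_bands:
            raise PipelineError(
                f"stage 'covariates': slope {slope!r} has {len(cov)} covariate rows "
                f"but the grid has {grid.n_bands} bands"
            )
        if config.global_split:
            groups = {
                "all": slope_ranges,
                "larger": [r for r in slope_ranges if (slope, r.species_id) in global_groups["larger"]],
                "smaller": [r for r in slope_ranges if (slope, r.species_id) in global_groups["smaller"]],
            }
        else:
            larger, smaller = median_split(slope_ranges, tie=config.median_tie)
            groups = {"all": slope_ranges, "larger": larger, "smaller": smaller}

        slope_report: dict[str, Any] = {"groups": {}}
        for group in config.groups:
            slope_report["groups"][group] = _analyse_group(
                slope, group, groups[group], grid, cov, config, out_dir
            )

        inc_all = build_incidence(grid, slope_ranges)
        realm_vecs = realm_richness(inc_all, {r.species_id: r.realm for r in slope_ranges})
        slope_report["realms"] = {}
        for realm, vec in realm_vecs.items():
            entry: dict[str, Any] = {"richness": vec.counts}
            if np.ptp(vec.counts) > 0:
                pf = polynomial_select(vec, grid.midpoints)
                entry["polynomial"] = {
                    "order": pf.order,
                    "r_squared": pf.r_squared,
                    "coefficients": pf.coefficients,
                }
            slope_report["realms"][realm] = entry
        slope_report["beta"] = _analyse_beta(slope, slope_ranges, grid, config, sites, out_dir)
        report["slopes"][slope] = slope_report

    # cross-slope comparisons (need exactly two slopes)
    if len(config.grids) == 2:
        (sa, ga), (sb, gb) = config.grids.items()
        report["cross_slope"] = _analyse_cross_slope(
            sa, sb, ga, gb, by_slope, cov_all, config, out_dir
        )

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


@_stage("cross_slope")
def _analyse_cross_slope(
    slope_a: str,
    slope_b: str,
    grid_a: ElevationGrid,
    grid_b: ElevationGrid,
    by_slope: Mapping[str, Sequence[SpeciesRange]],
    cov_all: pd.DataFrame,
    config: RunConfig,
    out_dir: Path,
) -> dict:
    pairing = pair_bands(grid_a, grid_b)
    inc_a = build_incidence(grid_a, list(by_slope[slope_a]))
    inc_b = build_incidence(grid_b, list(by_slope[slope_b]))
    cst = cross_slope_turnover(inc_a, inc_b, pairing)
    pd.DataFrame(
        {
            "elev_m": cst.elevations_m,
            f"band_{slope_a}": [i for i, _ in cst.pair_bands],
            f"band_{slope_b}": [j for _, j in cst.pair_bands],
            "sorensen": cst.dissimilarity,
        }
    ).to_csv(out_dir / "cross_slope_turnover.csv", index=False)

    cov_a = cov_all[cov_all["slope"] == slope_a].set_index("band_index")
    cov_b = cov_all[cov_all["slope"] == slope_b].set_index("band_index")
    ttests = {}
    for col in ("amt_c", "amp_mm", "evi", "area_km2"):
        x = np.array([cov_a.loc[i, col] for i, _ in pairing], dtype=float)
        y = np.array([cov_b.loc[j, col] for _, j in pairing], dtype=float)
        t = paired_t_test(x, y)
        ttests[col] = {"t": t.t, "df": t.df, "p": t.p, "degenerate": t.degenerate}

    return {
        "n_pairs": len(pairing),
        "shared_species": sorted(shared_species(by_slope[slope_a], by_slope[slope_b])),
        "n_shared": len(shared_species(by_slope[slope_a], by_slope[slope_b])),
        "turnover": cst.dissimilarity,
        "standardized_slope": cst.standardized_slope,
        "paired_t_tests": ttests,
    }
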