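"""Tabular I/O for species-range tables, per-band covariates, and distance
matrices.

Schemas (CSV, UTF-8, '.' decimal separator):

* ranges: ``species_id, slope, realm`` plus either ``band_list`` (semicolon
  separated 0-based band indices) or ``min_elev_m, max_elev_m`` (snapped to
  the bands containing them).
* covariates: ``slope, band_index, band_mid_m, amt_c, amp_mm, evi, area_km2``.
* distance matrix: labelled square CSV, symmetric, zero diagonal.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ElevationGrid, SpeciesRange

RANGE_BASE_COLUMNS = ("species_id", "slope", "realm")
COVARIATE_COLUMNS = ("slope", "band_index", "band_mid_m", "amt_c", "amp_mm", "evi", "area_km2")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file {path} is missing column(s): {', '.join(missing)}")


def read_ranges(path, grids: Mapping[str, ElevationGrid]) -> list[SpeciesRange]:
    """Read a species-range table.

    ``band_list`` takes precedence when both encodings are present.  If the
    file lacks a ``slope`` column the ranges are assumed to be pooled across
    slopes; a warning is emitted because per-slope analyses then cannot be
    separated, and the single grid in ``grids`` is used for every row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    if "slope" not in df.columns:
        if len(grids) != 1:
            raise ValueError(
                f"ranges file {path} has no 'slope' column (pooled ranges) but "
                f"{len(grids)} grids were supplied; pooled input needs exactly one grid"
            )
        warnings.warn(
            f"ranges file {path} has no 'slope' column: treating ranges as pooled "
            "across slopes; per-slope analyses are not separable",
            UserWarning,
            stacklevel=2,
        )
        df = df.assign(slope=next(iter(grids)))
    _require_columns(df, RANGE_BASE_COLUMNS, "ranges", path)
    has_bands = "band_list" in df.columns and df["band_list"].str.len().gt(0).any()
    has_elev = "min_elev_m" in df.columns and "max_elev_m" in df.columns
    if not has_bands and not has_elev:
        raise ValueError(
            f"ranges file {path} needs either a 'band_list' column or both "
            "'min_elev_m' and 'max_elev_m'"
        )

    dup = df.duplicated(subset=["species_id", "slope"])
    if dup.any():
        rows = df.loc[dup, ["species_id", "slope"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (species_id, slope) rows in {path}: {rows}")

    out: list[SpeciesRange] = []
    for _, row in df.iterrows():
        slope = row["slope"]
        if slope not in grids:
            raise ValueError(f"row for {row['species_id']!r} has unknown slope {slope!r}")
        grid = grids[slope]
        band_list = row.get("band_list", "")
        if band_list:
            try:
                bands = {int(tok) for tok in str(band_list).split(";") if tok != ""}
            except ValueError as exc:
                raise ValueError(
                    f"bad band_list {band_list!r} for species {row['species_id']!r}"
                ) from exc
        else:
            try:
                lo = float(row["min_elev_m"])
                hi = float(row["max_elev_m"])
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"non-numeric or missing elevations for species "
                    f"{row['species_id']!r} in {path}"
                ) from exc
            if hi < lo:
                raise ValueError(
                    f"max_elev_m < min_elev_m for species {row['species_id']!r}"
                )
            bands = {grid.band_containing(lo), grid.band_containing(hi)}
        if any(b < 0 or b >= grid.n_bands for b in bands):
            raise ValueError(
                f"band indices {sorted(bands)} out of range for slope {slope!r} "
                f"({grid.n_bands} bands)"
            )
        out.append(SpeciesRange(row["species_id"], slope, frozenset(bands), row["realm"]))
    return out


def write_ranges(ranges: Sequence[SpeciesRange], path, grids: Mapping[str, ElevationGrid]) -> None:
    """Write a species-range table (both band_list and elevation encodings)."""
    rows = []
    for r in sorted(ranges, key=lambda r: (r.slope_label, r.species_id)):
        grid = grids[r.slope_label]
        low, high = r.interpolated_interval
        rows.append(
            {
                "species_id": r.species_id,
                "slope": r.slope_label,
                "realm": r.realm,
                "band_list": ";".join(str(b) for b in sorted(r.observed_bands)),
                # midpoints so the elevation encoding snaps back to the same bands
                "min_elev_m": grid.midpoint(low),
                "max_elev_m": grid.midpoint(high),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read and validate a per-band covariate table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, COVARIATE_COLUMNS, "covariates", path)
    numeric = [c for c in COVARIATE_COLUMNS if c != "slope"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), col].tolist()
            raise ValueError(f"non-numeric values in covariates column {col!r}: {bad}")
        df[col] = vals
    if (df["area_km2"] < 0).any():
        raise ValueError("negative band areas in covariates file")
    if ((df["evi"] < -1) | (df["evi"] > 1)).any():
        raise ValueError("EVI values outside [-1, 1] in covariates file")
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df)[list(COVARIATE_COLUMNS)].to_csv(path, index=False)


def read_distance_matrix(path) -> pd.DataFrame:
    """Read a labelled square symmetric distance matrix (zero diagonal)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"distance matrix {path}: row and column labels differ")
    arr = df.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError(f"distance matrix {path} is not symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError(f"distance matrix {path} has a nonzero diagonal")
    return df


def write_distance_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path)
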