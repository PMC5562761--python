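"""Banded elevational domains, species ranges, and incidence matrices.

A mountain gradient is discretised into contiguous fixed-width elevational
bands (250 m by convention).  A species' elevational range is recorded as the
set of bands where it was detected; *range interpolation* assumes the species
occupies every band between its lowest and highest records, so each species
ends up occupying one contiguous run of bands.  Richness, realm tallies, and
range-size statistics are all computed from the resulting presence/absence
incidence matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REALMS = ("Oriental", "Palaearctic")

DEFAULT_BAND_WIDTH = 250.0


@dataclass(frozen=True)
class ElevationGrid:
    """The banded domain of one slope.

    Band ``i`` (0-based) covers the half-open interval
    ``[base + i*width, base + (i+1)*width)``; its midpoint is
    ``base + (i + 0.5)*width``.
    """

    slope_label: str
    base_elevation: float
    band_width: float
    n_bands: int

    def __post_init__(self) -> None:
        if self.band_width <= 0:
            raise ValueError(f"band_width must be positive, got {self.band_width}")
        if self.n_bands < 2:
            raise ValueError(
                f"grid needs at least 2 bands, got {self.n_bands} "
                f"(slope {self.slope_label!r})"
            )

    @property
    def top_elevation(self) -> float:
        return self.base_elevation + self.n_bands * self.band_width

    def band_start(self, i: int) -> float:
        self._check_index(i)
        return self.base_elevation + i * self.band_width

    def midpoint(self, i: int) -> float:
        self._check_index(i)
        return self.base_elevation + (i + 0.5) * self.band_width

    @property
    def midpoints(self) -> np.ndarray:
        return self.base_elevation + (np.arange(self.n_bands) + 0.5) * self.band_width

    @property
    def band_starts(self) -> np.ndarray:
        return self.base_elevation + np.arange(self.n_bands) * self.band_width

    def band_containing(self, elevation_m: float) -> int:
        """Index of the band containing an elevation.

        The domain top (``base + n_bands*width``) is snapped to the last band
        so that a record at the summit is usable.
        """
        if not (self.base_elevation <= elevation_m <= self.top_elevation):
            raise ValueError(
                f"elevation {elevation_m} m outside grid "
                f"[{self.base_elevation}, {self.top_elevation}] on slope "
                f"{self.slope_label!r}"
            )
        idx = int(math.floor((elevation_m - self.base_elevation) / self.band_width))
        return min(idx, self.n_bands - 1)

    def _check_index(self, i: int) -> None:
        if not (0 <= i < self.n_bands):
            raise IndexError(f"band index {i} out of range [0, {self.n_bands})")


def build_grid(
    slope_label: str,
    min_elev: float,
    max_elev: float,
    band_width: float = DEFAULT_BAND_WIDTH,
) -> ElevationGrid:
    """Tile ``[min_elev, max_elev]`` with contiguous bands of ``band_width``.

    ``n_bands = ceil((max_elev - min_elev) / band_width)`` so the last band
    may extend past ``max_elev``.
    """
    if band_width <= 0:
        raise ValueError(f"band_width must be positive, got {band_width}")
    if max_elev <= min_elev:
        raise ValueError(
            f"max_elev ({max_elev}) must exceed min_elev ({min_elev})"
        )
    n_bands = math.ceil((max_elev - min_elev) / band_width)
    return ElevationGrid(slope_label, float(min_elev), float(band_width), n_bands)


def interpolate_range(observed_bands: Iterable[int]) -> tuple[int, int]:
    """Fill gaps in an observed band set: a species found at both higher and
    lower elevations is assumed to occupy the bands in between.

    Returns the inclusive ``[min(observed), max(observed)]`` interval.
    """
    bands = set(int(b) for b in observed_bands)
    if not bands:
        raise ValueError("species has no observed bands; cannot interpolate")
    if any(b < 0 for b in bands):
        raise ValueError(f"negative band indices in {sorted(bands)}")
    return (min(bands), max(bands))


def range_size_bands(interval: tuple[int, int]) -> int:
    low, high = interval
    if high < low:
        raise ValueError(f"inverted interval [{low}, {high}]")
    return high - low + 1


def range_size_m(interval: tuple[int, int], band_width: float = DEFAULT_BAND_WIDTH) -> float:
    """Range size as n x band_width metres, n the number of occupied bands."""
    return range_size_bands(interval) * band_width


@dataclass(frozen=True)
class SpeciesRange:
    """One species' elevational occupancy on one slope."""

    species_id: str
    slope_label: str
    observed_bands: frozenset[int]
    realm: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed_bands", frozenset(int(b) for b in self.observed_bands))
        if not self.observed_bands:
            raise ValueError(f"species {self.species_id!r} has no observed bands")
        if self.realm not in REALMS:
            raise ValueError(
                f"unknown realm {self.realm!r} for species {self.species_id!r}; "
                f"expected one of {REALMS}"
            )

    @property
    def interpolated_interval(self) -> tuple[int, int]:
        return interpolate_range(self.observed_bands)

    @property
    def n_bands(self) -> int:
        return range_size_bands(self.interpolated_interval)

    def range_size_m(self, band_width: float = DEFAULT_BAND_WIDTH) -> float:
        return range_size_m(self.interpolated_interval, band_width)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Bands x species presence/absence after interpolation.

    Each species column is a contiguous run of True (guaranteed by
    construction from interpolated intervals).
    """

    grid: ElevationGrid
    presence: pd.DataFrame  # index: band, columns: species_id, dtype bool

    def __post_init__(self) -> None:
        if len(self.presence) != self.grid.n_bands:
            raise ValueError(
                f"presence table has {len(self.presence)} rows but grid has "
                f"{self.grid.n_bands} bands"
            )
        arr = self.presence.to_numpy(dtype=bool)
        for j, sp in enumerate(self.presence.columns):
            col = arr[:, j]
            occupied = np.flatnonzero(col)
            if occupied.size == 0:
                raise ValueError(f"species {sp!r} occupies no band")
            if occupied[-1] - occupied[0] + 1 != occupied.size:
                raise ValueError(f"species {sp!r} presence column is not contiguous")

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    def band_assemblage(self, i: int) -> set[str]:
        row = self.presence.iloc[i]
        return set(row.index[row])

    def range_sizes_bands(self) -> np.ndarray:
        return self.presence.to_numpy(dtype=int).sum(axis=0)


def build_incidence(grid: ElevationGrid, ranges: Sequence[SpeciesRange]) -> IncidenceMatrix:
    """Interpolated incidence matrix for the species of one slope."""
    seen: set[str] = set()
    cols = {}
    for r in ranges:
        if r.slope_label != grid.slope_label:
            raise ValueError(
                f"species {r.species_id!r} belongs to slope {r.slope_label!r}, "
                f"not {grid.slope_label!r}"
            )
        if r.species_id in seen:
            raise ValueError(f"duplicate species {r.species_id!r} on slope {grid.slope_label!r}")
        seen.add(r.species_id)
        low, high = r.interpolated_interval
        if high >= grid.n_bands:
            raise ValueError(
                f"species {r.species_id!r} occupies band {high} beyond the "
                f"{grid.n_bands}-band grid"
            )
        col = np.zeros(grid.n_bands, dtype=bool)
        col[low : high + 1] = True
        cols[r.species_id] = col
    index = pd.RangeIndex(grid.n_bands, name="band_index")
    presence = pd.DataFrame(cols, index=index, dtype=bool)
    return IncidenceMatrix(grid, presence)


@dataclass(frozen=True)
class RichnessVector:
    grid: ElevationGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.grid.n_bands,):
            raise ValueError("richness length must equal number of bands")
        if (counts < 0).any():
            raise ValueError("richness counts must be nonnegative")


def richness(incidence: IncidenceMatrix) -> RichnessVector:
    """Per-band species counts: row sums of the incidence matrix."""
    counts = incidence.presence.to_numpy(dtype=int).sum(axis=1)
    return RichnessVector(incidence.grid, counts)


def median_split(
    ranges: Sequence[SpeciesRange],
    tie: str = "smaller",
) -> tuple[list[SpeciesRange], list[SpeciesRange]]:
    """Split species into larger-ranged and smaller-ranged halves at the
    median range size.

    Species strictly above the median go to the larger-ranged set.  Species
    exactly at the median go to the smaller-ranged set by default (so the
    larger set strictly satisfies "above the median"); ``tie='larger'``
    reverses that.
    """
    if len(ranges) < 2:
        raise ValueError("median split needs at least 2 species")
    if tie not in ("smaller", "larger"):
        raise ValueError(f"tie must be 'smaller' or 'larger', got {tie!r}")
    sizes = np.array([r.n_bands for r in ranges], dtype=float)
    med = float(np.median(sizes))
    larger, smaller = [], []
    for r, s in zip(ranges, sizes):
        if s > med or (tie == "larger" and s == med):
            larger.append(r)
        else:
            smaller.append(r)
    return larger, smaller


def realm_richness(
    incidence: IncidenceMatrix,
    realms: Mapping[str, str],
) -> dict[str, RichnessVector]:
    """Per-band richness of Oriental and Palaearctic species separately.

    The two vectors sum to the total richness per band.
    """
    arr = incidence.presence.to_numpy(dtype=int)
    out = {}
    masks = {realm: np.zeros(incidence.n_species, dtype=bool) for realm in REALMS}
    for j, sp in enumerate(incidence.species):
        if sp not in realms:
            raise ValueError(f"species {sp!r} has no realm label")
        realm = realms[sp]
        if realm not in REALMS:
            raise ValueError(f"unknown realm {realm!r} for species {sp!r}")
        masks[realm][j] = True
    for realm, mask in masks.items():
        counts = arr[:, mask].sum(axis=1) if mask.any() else np.zeros(len(arr), dtype=int)
        out[realm] = RichnessVector(incidence.grid, counts)
    return out


def shared_species(
    slope_a_ranges: Sequence[SpeciesRange],
    slope_b_ranges: Sequence[SpeciesRange],
) -> set[str]:
    """Species recorded on both slopes (intersection of species ids)."""
    return {r.species_id for r in slope_a_ranges} & {r.species_id for r in slope_b_ranges}
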