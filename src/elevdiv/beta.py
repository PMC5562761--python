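"""Species-turnover (beta-diversity) statistics on banded gradients.

Sorensen dissimilarity S = (b + c) / (2a + b + c) between two assemblages
(a shared species, b and c unique to each side) is computed for adjacent
band pairs, for every band pair (a dissimilarity matrix), and for bands
matched on elevation across slopes.  Whittaker's index W = s/alpha - 1
summarises turnover at the whole-gradient scale.  Distance decay of
similarity is tested with a one-tailed Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import IncidenceMatrix
from .inference import PolynomialFit, polynomial_select


def sorensen(a: int, b: int, c: int) -> float:
    """Sorensen dissimilarity from shared (a) and unique (b, c) counts.

    0 for identical composition, 1 for disjoint assemblages.
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("species counts must be nonnegative")
    if a + b == 0 or a + c == 0:
        raise ValueError("Sorensen undefined when an assemblage is empty")
    return (b + c) / (2 * a + b + c)


def sorensen_sets(s1: set, s2: set) -> float:
    a = len(s1 & s2)
    return sorensen(a, len(s1) - a, len(s2) - a)


def _abc(presence: np.ndarray, i: int, j: int) -> tuple[int, int, int]:
    p, q = presence[i], presence[j]
    a = int(np.sum(p & q))
    return a, int(np.sum(p & ~q)), int(np.sum(~p & q))


def adjacent_turnover(incidence: IncidenceMatrix) -> np.ndarray:
    """Sorensen dissimilarity for each consecutive band pair.

    Length ``n_bands - 1``; comparisons involving an empty band are NaN.
    """
    pres = incidence.presence.to_numpy(dtype=bool)
    n = pres.shape[0]
    if n < 2:
        raise ValueError("need at least 2 bands")
    out = np.full(n - 1, np.nan)
    for i in range(n - 1):
        a, b, c = _abc(pres, i, i + 1)
        if a + b == 0 or a + c == 0:
            continue  # empty band: comparison reported as missing
        out[i] = sorensen(a, b, c)
    return out


@dataclass(frozen=True)
class DissimilarityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        off = v[~np.eye(n, dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("dissimilarities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def dissimilarity_matrix(incidence: IncidenceMatrix) -> DissimilarityMatrix:
    """Full Sorensen dissimilarity matrix between all band pairs of a slope."""
    pres = incidence.presence.to_numpy(dtype=bool)
    n = pres.shape[0]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b, c = _abc(pres, i, j)
            vals[i, j] = vals[j, i] = sorensen(a, b, c) if (a + b and a + c) else np.nan
    labels = tuple(f"band{i}" for i in range(n))
    return DissimilarityMatrix(labels, vals)


@dataclass(frozen=True)
class CrossSlopeTurnover:
    pair_bands: tuple[tuple[int, int], ...]
    elevations_m: np.ndarray  # shared band-start elevations
    dissimilarity: np.ndarray
    standardized_slope: float | None  # Pearson r of dissimilarity vs elevation; None if constant


def cross_slope_turnover(
    incidence_a: IncidenceMatrix,
    incidence_b: IncidenceMatrix,
    pairing: Sequence[tuple[int, int]],
) -> CrossSlopeTurnover:
    """Sorensen dissimilarity between band pairs matched on elevation across
    slopes, plus the standardized regression slope of dissimilarity on
    elevation (equal to the Pearson correlation)."""
    if len(pairing) < 3:
        raise ValueError("need at least 3 matched band pairs")
    # realign columns on the union species list so shared species line up
    union = sorted(set(incidence_a.species) | set(incidence_b.species))
    da = incidence_a.presence.reindex(columns=union, fill_value=False).to_numpy(dtype=bool)
    db = incidence_b.presence.reindex(columns=union, fill_value=False).to_numpy(dtype=bool)
    diss = []
    elevs = []
    for i, j in pairing:
        p, q = da[i], db[j]
        a = int(np.sum(p & q))
        b = int(np.sum(p & ~q))
        c = int(np.sum(~p & q))
        diss.append(sorensen(a, b, c) if (a + b and a + c) else np.nan)
        elevs.append(incidence_a.grid.band_start(i))
    diss = np.asarray(diss)
    elevs = np.asarray(elevs, dtype=float)
    ok = np.isfinite(diss)
    if ok.sum() >= 3 and np.ptp(diss[ok]) > 0 and np.ptp(elevs[ok]) > 0:
        slope = float(stats.pearsonr(elevs[ok], diss[ok]).statistic)
    else:
        slope = None  # constant dissimilarity: standardized slope undefined
    return CrossSlopeTurnover(tuple(pairing), elevs, diss, slope)


def whittaker(s: float, alpha: float) -> float:
    """Whittaker beta diversity W = s/alpha - 1 (regional over mean local)."""
    if alpha <= 0:
        raise ValueError("mean local richness alpha must be positive")
    if s < alpha:
        raise ValueError(f"total richness s ({s}) cannot be below alpha ({alpha})")
    return s / alpha - 1.0


def whittaker_from_sites(site_table: pd.DataFrame) -> float:
    """Whittaker index with alpha = mean species count per site.

    ``site_table`` needs columns ``site_id`` and ``species_id`` (one row per
    detection).
    """
    for col in ("site_id", "species_id"):
        if col not in site_table.columns:
            raise ValueError(f"site table is missing column {col!r}")
    if site_table.empty:
        raise ValueError("site table has no detections")
    s = site_table["species_id"].nunique()
    alpha = float(site_table.groupby("site_id")["species_id"].nunique().mean())
    return whittaker(s, alpha)


def whittaker_from_incidence(incidence: IncidenceMatrix) -> float:
    """Band-level fallback: alpha = mean per-band richness."""
    counts = incidence.presence.to_numpy(dtype=int).sum(axis=1)
    return whittaker(incidence.n_species, float(counts.mean()))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    tail: str


def mantel(
    d1: DissimilarityMatrix | pd.DataFrame | np.ndarray,
    d2: DissimilarityMatrix | pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Simple Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; rows and
    columns of the second matrix are permuted jointly.  The default tail
    tests for positive association (distance decay is directional);
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1) so p is never 0.
    """
    m1, labels1 = _as_matrix(d1)
    m2, labels2 = _as_matrix(d2)
    if labels1 is not None and labels2 is not None and labels1 != labels2:
        raise ValueError("matrix labels do not match")
    if m1.shape != m2.shape:
        raise ValueError("matrices must have the same shape")
    n = m1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"tail must be 'greater' or 'two-sided', got {tail!r}")
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]
    if np.ptp(v1) == 0 or np.ptp(m2[iu]) == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    r_obs = float(stats.pearsonr(v1, m2[iu]).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = m2[np.ix_(perm, perm)][iu]
        r_p = float(stats.pearsonr(v1, v2p).statistic)
        if tail == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed, tail=tail)


def _as_matrix(d) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(d, DissimilarityMatrix):
        return d.values, d.labels
    if isinstance(d, pd.DataFrame):
        return d.to_numpy(dtype=float), tuple(map(str, d.index))
    return np.asarray(d, dtype=float), None


def turnover_elevation_fit(
    turnover: Sequence[float],
    elevation: Sequence[float],
) -> PolynomialFit:
    """Polynomial regression (orders 1-3, AICc-selected) of turnover on the
    elevation of each band boundary."""
    t = np.asarray(turnover, dtype=float)
    e = np.asarray(elevation, dtype=float)
    ok = np.isfinite(t)
    if ok.sum() < 6:
        raise ValueError("need at least 6 finite turnover values")
    return polynomial_select(t[ok], e[ok])
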