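"""Per-band environmental covariates and between-slope comparisons.

Annual mean temperature (AMT) comes from empirical linear lapse models fitted
to in-situ logger data on each slope; precipitation (AMP), vegetation index
(EVI) and band surface area are externally derived inputs and are never
computed here.  Between-slope contrasts use paired t-tests over bands matched
on identical band-start elevation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core import ElevationGrid


@dataclass(frozen=True)
class LapseModel:
    """Linear decline of AMT with altitude: AMT = coefficient * altitude + intercept."""

    slope_coefficient: float  # degrees C per metre
    intercept: float  # degrees C at sea level


# lapse models for the two slopes of the study massif (degrees C)
NORTH_LAPSE = LapseModel(-0.0049, 17.9)
SOUTH_LAPSE = LapseModel(-0.0037, 14.5)


def amt_at(altitude_m, model: LapseModel):
    """AMT (deg C) at an altitude from the lapse model."""
    altitude_m = np.asarray(altitude_m, dtype=float)
    if (altitude_m < 0).any():
        raise ValueError("altitude must be nonnegative")
    out = model.slope_coefficient * altitude_m + model.intercept
    return float(out) if out.ndim == 0 else out


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool  # True when the differences have zero variance


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Paired-samples t-test on band-matched covariate vectors.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y, df = n - 1, two-sided p.
    Zero-variance differences with nonzero mean give an infinite t (flagged
    via ``degenerate``); identical vectors give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            return PairedTResult(0.0, n - 1, 1.0, True)
        return PairedTResult(float(np.sign(np.mean(d)) * np.inf), n - 1, 0.0, True)
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), n - 1, float(res.pvalue), False)


def pair_bands(grid_a: ElevationGrid, grid_b: ElevationGrid) -> list[tuple[int, int]]:
    """Match bands across slopes on identical band-start elevation.

    For the default grids (south 1250-3650 m, north 1000-3700 m, 250-m bands)
    the shared span yields 10 matched pairs.
    """
    if grid_a.band_width != grid_b.band_width:
        raise ValueError("grids must share the band width to be paired")
    starts_b = {grid_b.band_start(j): j for j in range(grid_b.n_bands)}
    pairs = [
        (i, starts_b[grid_a.band_start(i)])
        for i in range(grid_a.n_bands)
        if grid_a.band_start(i) in starts_b
    ]
    if not pairs:
        raise ValueError(
            f"no overlapping band elevations between slopes "
            f"{grid_a.slope_label!r} and {grid_b.slope_label!r}"
        )
    return pairs
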