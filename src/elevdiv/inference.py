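"""AICc multi-model inference over per-band predictors.

All 2^p - 1 non-empty subsets of the standardized predictors are fitted by
OLS, ranked by the small-sample Akaike criterion, and summarised by Akaike
weights, per-predictor impact factors (variable importance), and
model-averaged standardized coefficients.  Polynomial richness-elevation
models (orders 1-3) are selected the same way.

AICc uses the Gaussian profile log-likelihood form
``AIC = n ln(rss/n) + 2k`` with k counting intercept + slope coefficients +
the error variance, plus the correction ``2k(k+1)/(n-k-1)``.  No p-values are
attached to the multi-model outputs: with ~10 spatially autocorrelated bands
per gradient they would be unreliable, so p-values appear only in single-fit
polynomial and observed-vs-null regressions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .core import RichnessVector

RSS_FLOOR = 1e-12
IMPORTANCE_THRESHOLD = 0.80


def standardize(values: Sequence[float]) -> np.ndarray:
    """z-score: mean 0, sample (ddof=1) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample Akaike criterion for a Gaussian OLS fit.

    rss below 1e-12 is clamped to 1e-12 so perfect fits stay finite.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1 (n={n}, k={k})")
    rss = max(float(rss), RSS_FLOOR)
    aic = n * math.log(rss / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Normalized evidence w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValueError("empty model set")
    delta = a - a.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


@dataclass(frozen=True)
class OLSFit:
    predictor_subset: tuple[str, ...]
    k: int  # intercept + coefficients + error variance
    rss: float
    aicc: float
    r_squared: float
    std_betas: dict[str, float]
    std_errors: dict[str, float]
    collinear: bool = False


@dataclass(frozen=True)
class ModelSet:
    fits: tuple[OLSFit, ...]
    delta_aicc: np.ndarray
    weights: np.ndarray
    impact_factors: dict[str, float]
    important: dict[str, bool]
    averaged_betas: dict[str, float]
    averaged_se: dict[str, float]
    best: OLSFit

    @property
    def predictors(self) -> list[str]:
        return list(self.impact_factors)


def _fit_subset(y: np.ndarray, X: dict[str, np.ndarray], subset: tuple[str, ...], n: int) -> OLSFit:
    design = sm.add_constant(np.column_stack([X[p] for p in subset]))
    collinear = np.linalg.matrix_rank(design) < design.shape[1]
    if collinear:
        warnings.warn(
            f"collinear predictors in subset {subset}; fitted via pseudo-inverse",
            UserWarning,
            stacklevel=3,
        )
    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    k = len(subset) + 2
    return OLSFit(
        predictor_subset=subset,
        k=k,
        rss=rss,
        aicc=aicc(rss, n, k),
        r_squared=float(res.rsquared),
        std_betas={p: float(b) for p, b in zip(subset, res.params[1:])},
        std_errors={p: float(se) for p, se in zip(subset, res.bse[1:])},
        collinear=collinear,
    )


def all_subsets(
    response: RichnessVector | Sequence[float],
    predictors: Mapping[str, Sequence[float]],
    *,
    standardize_inputs: bool = True,
    full_model_average: bool = False,
) -> ModelSet:
    """Fit every non-empty predictor subset (31 models for 5 predictors).

    Response and predictors are z-scored before fitting so the coefficients
    are standardized betas.  Weights, impact factors, and model-averaged
    coefficients are computed over the whole set.
    """
    y = np.asarray(response.counts if isinstance(response, RichnessVector) else response, dtype=float)
    names = list(predictors)
    p = len(names)
    n = y.size
    if p < 1:
        raise ValueError("need at least one predictor")
    # largest model has k = p + 2; AICc needs n > k + 1
    if n < p + 4:
        raise ValueError(
            f"need at least {p + 4} bands for {p} predictors "
            f"(largest model k={p + 2} requires n > k + 1), got {n}"
        )
    X = {}
    for name in names:
        v = np.asarray(predictors[name], dtype=float)
        if v.shape != y.shape:
            raise ValueError(f"predictor {name!r} length {v.size} != response length {n}")
        X[name] = standardize(v) if standardize_inputs else v
    if standardize_inputs:
        y = standardize(y)

    fits = tuple(
        _fit_subset(y, X, subset, n)
        for size in range(1, p + 1)
        for subset in itertools.combinations(names, size)
    )
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    weights = akaike_weights(aiccs)
    best = fits[int(np.argmin(aiccs))]

    impact = impact_factors_from(fits, weights, names)
    important = {name: impact[name] >= IMPORTANCE_THRESHOLD for name in names}
    avg_b, avg_se = model_average_from(fits, weights, names, full=full_model_average)
    return ModelSet(
        fits=fits,
        delta_aicc=delta,
        weights=weights,
        impact_factors=impact,
        important=important,
        averaged_betas=avg_b,
        averaged_se=avg_se,
        best=best,
    )


def impact_factors_from(
    fits: Sequence[OLSFit], weights: Sequence[float], names: Sequence[str]
) -> dict[str, float]:
    """Variable importance: the summed Akaike weights of the models that
    include each predictor."""
    out = {}
    for name in names:
        out[name] = float(
            sum(w for f, w in zip(fits, weights) if name in f.predictor_subset)
        )
    return out


def impact_factors(model_set: ModelSet) -> dict[str, float]:
    return dict(model_set.impact_factors)


def model_average_from(
    fits: Sequence[OLSFit],
    weights: Sequence[float],
    names: Sequence[str],
    *,
    full: bool = False,
) -> tuple[dict[str, float], dict[str, float]]:
    """Model-averaged standardized coefficients and unconditional SEs.

    Natural averaging (default) conditions on the models containing the
    predictor, renormalising their weights; ``full=True`` instead averages
    over all models with beta = 0 where the predictor is absent.  SEs follow
    Buckland's combination sqrt(se^2 + (beta - beta_bar)^2) averaged with the
    same weights.
    """
    betas: dict[str, float] = {}
    ses: dict[str, float] = {}
    for name in names:
        b = np.array([f.std_betas.get(name, 0.0) for f in fits])
        se = np.array([f.std_errors.get(name, 0.0) for f in fits])
        w = np.asarray(weights, dtype=float)
        if not full:
            mask = np.array([name in f.predictor_subset for f in fits])
            if not mask.any():
                betas[name], ses[name] = 0.0, 0.0
                continue
            b, se, w = b[mask], se[mask], w[mask]
            w = w / w.sum()
        bbar = float(np.sum(w * b))
        betas[name] = bbar
        ses[name] = float(np.sum(w * np.sqrt(se**2 + (b - bbar) ** 2)))
    return betas, ses


def model_average(model_set: ModelSet) -> tuple[dict[str, float], dict[str, float]]:
    return dict(model_set.averaged_betas), dict(model_set.averaged_se)


@dataclass(frozen=True)
class PolynomialFit:
    """AICc-selected polynomial of the response on centred elevation."""

    order: int
    coefficients: np.ndarray  # intercept first, on centred elevation
    r_squared: float
    p_values: np.ndarray  # per coefficient, intercept first
    aicc_by_order: dict[int, float]


def polynomial_select(
    response: RichnessVector | Sequence[float],
    elevation: Sequence[float],
    max_order: int = 3,
) -> PolynomialFit:
    """Fit polynomials of order 1..3 on centred elevation, select by AICc.

    Orders whose AICc correction is undefined at the given n (n <= k + 1)
    are not candidates.
    """
    y = np.asarray(response.counts if isinstance(response, RichnessVector) else response, dtype=float)
    x = np.asarray(elevation, dtype=float)
    if y.shape != x.shape:
        raise ValueError("response and elevation must have equal length")
    if y.size < 6:
        raise ValueError(f"need at least 6 points, got {y.size}")
    xc = x - x.mean()
    results = {}
    scores: dict[int, float] = {}
    for order in range(1, max_order + 1):
        k = order + 2
        if y.size <= k + 1:
            continue
        design = np.column_stack([xc**d for d in range(order + 1)])
        res = sm.OLS(y, design).fit()
        scores[order] = aicc(float(res.ssr), y.size, k)
        results[order] = res
    if not scores:
        raise ValueError("no polynomial order satisfies the AICc sample-size condition")
    best_order = min(scores, key=scores.get)
    res = results[best_order]
    return PolynomialFit(
        order=best_order,
        coefficients=np.asarray(res.params, dtype=float),
        r_squared=float(res.rsquared),
        p_values=np.asarray(res.pvalues, dtype=float),
        aicc_by_order=scores,
    )
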