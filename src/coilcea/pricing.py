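"""Value-based pricing: maximum cost-effective adjunct price versus efficacy.

For a fixed relative risk reduction x and threshold lambda, the maximum
price y a payer can pay while keeping the probability of cost-effectiveness
at or above one half is the median over PSA iterations of
``lambda * dQALY - dCost0`` (with the adjunct price excluded from costs),
floored at zero: the price enters the incremental cost additively, once, at
cycle 0, undiscounted, so ``P(NMB > 0) >= 0.5  <=>  y <= median``.
Sweeping x from 0 to 1 in 1% steps traces the price-elasticity curve; a
least-squares line through the origin summarises it as ``y = slope * x``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .config import STRATEGY_HTI, STRATEGY_STANDARD, ModelConfig
from .errors import DegenerateFitError, ValidationError
from .markov import _evaluate  # vectorized single-arm engine
from .parameters import DrawSet, HtiEfficacySpec, ParameterSpec
from .psa import PsaSampleSet, draw_feasible

__all__ = ["ElasticityCurve", "max_price_at", "max_price_bisect",
           "elasticity_curve", "fit_through_origin"]


@dataclass(frozen=True)
class ElasticityCurve:
    """Maximum cost-effective price at each efficacy level, plus a linear fit."""

    threshold: float
    rrr: np.ndarray  # efficacy grid (fractions)
    max_price: np.ndarray  # USD per procedure
    fitted_slope: float  # USD per unit of relative risk reduction

    def price_at(self, rrr: float) -> float:
        """Fitted maximum price for a given efficacy: ``slope * rrr``."""
        return self.fitted_slope * rrr


def max_price_at(psa: PsaSampleSet, threshold: float) -> float:
    """Largest adjunct price keeping P(cost-effective) >= 0.5.

    ``psa`` must have been generated with the efficacy fixed and the adjunct
    price excluded from costs; the result is the median incremental net
    benefit, floored at zero.  With an even iteration count the upper middle
    order statistic is the exact supremum (the midpoint average would fall
    strictly below the acceptability condition), so the upper median is used.
    """
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    med = np.quantile(psa.nmb(threshold), 0.5, method="higher")
    return float(max(med, 0.0))


def max_price_bisect(
    psa: PsaSampleSet, threshold: float, tol: float = 0.5, p_max: float = 1e6
) -> float:
    """Brute-force bisection oracle for :func:`max_price_at`.

    Searches the largest price p with ``P(threshold*dE - dC0 - p > 0) >= 0.5``
    by re-evaluating the acceptability fraction at every candidate price.
    """
    nmb = psa.nmb(threshold)

    def acceptable(p: float) -> bool:
        return float((nmb - p > 0).mean()) >= 0.5

    if not acceptable(0.0):
        return 0.0
    lo, hi = 0.0, p_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if acceptable(mid):
            lo = mid
        else:
            hi = mid
    return lo


def fit_through_origin(points: Sequence[tuple[float, float]]) -> float:
    """Least-squares slope of a zero-intercept line: ``sum(xy) / sum(x^2)``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise DegenerateFitError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float((x * x).sum())
    if sxx == 0.0:
        raise DegenerateFitError("all x values are zero; slope is undefined")
    return float((x * y).sum() / sxx)


def elasticity_curve(
    specs: Sequence[ParameterSpec],
    config: ModelConfig,
    threshold: float,
    n_iterations: int = 2_000,
    seed: Optional[int] = None,
    rrr_grid: Optional[np.ndarray] = None,
) -> ElasticityCurve:
    """Sweep the efficacy grid and compute the maximum price at each point.

    One common draw set (with the adjunct price excluded) is shared across
    all grid points: the standard arm is evaluated once, and only the
    adjunct arm is re-propagated per efficacy value, which both speeds the
    sweep up and smooths the curve.
    """
    if rrr_grid is None:
        rrr_grid = np.round(np.linspace(0.0, 1.0, 101), 2)
    cfg = replace(config, hti_price=0.0)
    rng = np.random.default_rng(seed)
    ds, _ = draw_feasible(specs, HtiEfficacySpec("fixed", fixed_value=0.0),
                          n_iterations, rng)
    cost_std, qaly_std, _, _, _ = _evaluate(ds, cfg, STRATEGY_STANDARD)

    prices = np.empty(len(rrr_grid))
    for k, x in enumerate(rrr_grid):
        ds.rrr[:] = x
        cost_hti, qaly_hti, _, _, _ = _evaluate(ds, cfg, STRATEGY_HTI)
        nmb = threshold * (qaly_hti - qaly_std) - (cost_hti - cost_std)
        prices[k] = max(float(np.quantile(nmb, 0.5, method="higher")), 0.0)

    slope = fit_through_origin(list(zip(rrr_grid, prices)))
    return ElasticityCurve(
        threshold=threshold,
        rrr=np.asarray(rrr_grid, dtype=float),
        max_price=prices,
        fitted_slope=slope,
    )
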