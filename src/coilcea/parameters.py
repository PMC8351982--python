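"""Parameter registry and probabilistic sampling.

The model is driven by 25 parameters: eleven transition probabilities,
seven costs (2018 USD), five utilities, and the two adjunct (HTI)
parameters -- its efficacy, expressed as a relative risk reduction (RRR) of
recanalization, and its per-procedure price.  Each stochastic parameter is
published as a point value with a standard error and a distribution family;
distribution parameters are recovered here by moment matching.

Families
--------
beta
    Probabilities (and the magnitude of the untreated-aneurysm disutility,
    which is drawn as a Beta magnitude and returned negative).
gamma
    Right-skewed positive costs (aSAH hospital care).
truncated_ordered_normal
    Normals truncated to natural bounds (costs >= 0, utilities in [0, 1]);
    parameters sharing an ``order_group`` are drawn jointly by rejection
    until their values preserve the ordering of their means.
uniform / deterministic
    The HTI efficacy and price rows.

Probabilities are quoted over heterogeneous horizons (per procedure, per
year, per 6 years); :func:`per_cycle_probability` rescales them to the model
cycle under a constant-hazard assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateProbabilityError,
    InfeasibleMomentsError,
    SamplingFailureError,
    SchemaError,
)

__all__ = [
    "ParameterSpec",
    "HtiEfficacySpec",
    "ParameterDraw",
    "DrawSet",
    "MRS0_UTILITY_BANDS",
    "load_parameter_table",
    "default_parameter_table",
    "beta_from_moments",
    "gamma_from_moments",
    "truncated_normal_from_moments",
    "sample_ordered_truncated_normal_group",
    "sample_draw",
    "sample_draws",
    "per_cycle_probability",
    "expected_recanalization_with_hti",
]

DIST_FAMILIES = {"beta", "gamma", "truncated_ordered_normal", "uniform", "deterministic"}
GROUPS = {"probability", "cost", "utility", "hti"}

#: Utility of a coiled patient with good function (mRS 0) by age band.  The
#: published table gives one SE (0.01) for all four bands; a single draw of
#: the 45-54 value shifts every band by the same offset, preserving the
#: printed between-band differences.
MRS0_UTILITY_BANDS: tuple[tuple[float, float, float], ...] = (
    (45.0, 55.0, 0.87),
    (55.0, 65.0, 0.85),
    (65.0, 75.0, 0.86),
    (75.0, math.inf, 0.84),
)

DISUTILITY_ID = 22
RRR_ID = 24
HTI_PRICE_ID = 25
ORDERED_GROUP_RETRY_BUDGET = 10_000


@dataclass(frozen=True)
class ParameterSpec:
    """One row of the parameter table."""

    id: int
    name: str
    mean: float
    se: float
    dist_family: str
    source_duration_years: float = 0.0
    sens_low: float = math.nan
    sens_high: float = math.nan
    group: str = "probability"
    order_group: Optional[str] = None
    order_rank: Optional[int] = None

    def __post_init__(self):
        if self.dist_family not in DIST_FAMILIES:
            raise SchemaError(f"row {self.id}: unknown dist_family {self.dist_family!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"row {self.id}: unknown group {self.group!r}")
        if self.se < 0:
            raise SchemaError(f"row {self.id}: negative SE")
        if self.group == "probability" and not 0.0 <= self.mean <= 1.0:
            raise SchemaError(f"row {self.id}: probability mean outside [0,1]")
        if self.group == "cost" and self.mean < 0:
            raise SchemaError(f"row {self.id}: negative cost mean")


@dataclass(frozen=True)
class HtiEfficacySpec:
    """Distribution of the adjunct's relative risk reduction of recanalization.

    ``uniform01`` is the base case (all efficacies equally plausible),
    ``bounded_normal`` a normal(mu, sigma) truncated to [0, 1], and
    ``fixed`` a degenerate value (used by the price-elasticity sweep).
    """

    family: str = "uniform01"
    mu: float = 0.5
    sigma: float = 0.15
    fixed_value: float = 0.0

    def __post_init__(self):
        if self.family not in {"uniform01", "bounded_normal", "fixed"}:
            raise SchemaError(f"unknown HTI efficacy family {self.family!r}")
        if self.family == "fixed" and not 0.0 <= self.fixed_value <= 1.0:
            raise SchemaError("fixed RRR must lie in [0,1]")
        if self.family == "bounded_normal" and self.sigma <= 0:
            raise SchemaError("bounded_normal sigma must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.fixed_value)
        if self.family == "uniform01":
            return rng.uniform(0.0, 1.0, n)
        a = (0.0 - self.mu) / self.sigma
        b = (1.0 - self.mu) / self.sigma
        return stats.truncnorm.ppf(rng.uniform(size=n), a, b, loc=self.mu, scale=self.sigma)


@dataclass(frozen=True)
class ParameterDraw:
    """One realization of every parameter plus the HTI efficacy draw."""

    values: Mapping[int, float]
    rrr: float
    mrs0_by_band: tuple[float, ...] = ()

    def __getitem__(self, pid: int) -> float:
        return self.values[pid]

    def mrs0_utility(self, age: float) -> float:
        """mRS 0 utility for the band containing ``age`` (bands half-open)."""
        for (lo, hi, _), v in zip(MRS0_UTILITY_BANDS, self.mrs0_by_band):
            if lo <= age < hi:
                return v
        return self.mrs0_by_band[-1]


class DrawSet:
    """A vectorized batch of :class:`ParameterDraw` realizations.

    Stores one numpy array per parameter id (shape ``(n,)``) plus the
    per-band mRS 0 utilities and the RRR draws; this is the engine's native
    input so a PSA can propagate thousands of draws at once.
    """

    def __init__(self, values: dict[int, np.ndarray], rrr: np.ndarray, mrs0_bands: np.ndarray):
        self.values = values
        self.rrr = np.asarray(rrr, dtype=float)
        self.mrs0_bands = np.asarray(mrs0_bands, dtype=float)  # (n, 4)
        self.n = len(self.rrr)

    def __len__(self) -> int:
        return self.n

    def row(self, k: int) -> ParameterDraw:
        return ParameterDraw(
            values={pid: float(a[k]) for pid, a in self.values.items()},
            rrr=float(self.rrr[k]),
            mrs0_by_band=tuple(self.mrs0_bands[k]),
        )

    @classmethod
    def from_draw(cls, draw: ParameterDraw) -> "DrawSet":
        return cls(
            {pid: np.array([v], dtype=float) for pid, v in draw.values.items()},
            np.array([draw.rrr], dtype=float),
            np.array([draw.mrs0_by_band], dtype=float),
        )

    def overwrite(self, mask: np.ndarray, other: "DrawSet") -> None:
        """Replace the rows selected by ``mask`` with the rows of ``other``."""
        idx = np.flatnonzero(mask)
        for pid in self.values:
            self.values[pid][idx] = other.values[pid]
        self.rrr[idx] = other.rrr
        self.mrs0_bands[idx] = other.mrs0_bands


# ---------------------------------------------------------------------------
# table loading


_NUMERIC_COLS = ["id", "mean", "se", "source_duration_years", "sens_low", "sens_high"]
_REQUIRED_COLS = [
    "id", "name", "mean", "se", "dist_family", "source_duration_years",
    "sens_low", "sens_high", "group", "order_group", "order_rank",
]


def load_parameter_table(path=None) -> list[ParameterSpec]:
    """Read a parameter table CSV; with no argument, the bundled default.

    The bundled default reproduces the published 25-row table (means, SEs,
    families, sensitivity bounds).  Raises :class:`SchemaError` on missing or
    duplicated ids, missing columns, or non-numeric fields, naming the row.
    """
    if path is None:
        with resources.files("coilcea.data").joinpath("parameters.csv").open("rb") as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter table missing columns: {missing}")
    for col in _NUMERIC_COLS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(f"non-numeric {col!r} in table row {bad[0] + 1}")
        df[col] = coerced
    if df["id"].isna().any():
        raise SchemaError("parameter table has a row with a missing id")
    ids = df["id"].astype(int)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate parameter id {int(dup.iloc[0])}")
    if sorted(ids) != list(range(1, 26)):
        raise SchemaError(f"expected ids 1..25, got {sorted(ids)}")

    specs = []
    for _, r in df.iterrows():
        og = r["order_group"] if isinstance(r["order_group"], str) and r["order_group"] else None
        rank = int(r["order_rank"]) if pd.notna(r["order_rank"]) else None
        specs.append(
            ParameterSpec(
                id=int(r["id"]),
                name=str(r["name"]),
                mean=float(r["mean"]),
                se=float(r["se"]),
                dist_family=str(r["dist_family"]),
                source_duration_years=float(r["source_duration_years"]),
                sens_low=float(r["sens_low"]) if pd.notna(r["sens_low"]) else math.nan,
                sens_high=float(r["sens_high"]) if pd.notna(r["sens_high"]) else math.nan,
                group=str(r["group"]),
                order_group=og,
                order_rank=rank,
            )
        )
    specs.sort(key=lambda s: s.id)
    _validate_order_groups(specs)
    return specs


def default_parameter_table() -> list[ParameterSpec]:
    return load_parameter_table(None)


def _validate_order_groups(specs: Sequence[ParameterSpec]) -> None:
    groups: dict[str, list[ParameterSpec]] = {}
    for s in specs:
        if s.order_group:
            groups.setdefault(s.order_group, []).append(s)
    for name, members in groups.items():
        ranks = [m.order_rank for m in members]
        if None in ranks or len(set(ranks)) != len(ranks):
            raise SchemaError(f"order group {name!r} has missing or duplicate ranks")


# ---------------------------------------------------------------------------
# moment matching


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the given mean and variance ``se**2``.

    Uses nu = mean(1-mean)/se^2 - 1, alpha = mean*nu, beta = (1-mean)*nu.
    Infeasible when se^2 >= mean(1-mean) (the Bernoulli variance bound).
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean {mean} outside (0,1)")
    if se <= 0:
        raise InfeasibleMomentsError("beta SE must be positive")
    if se * se >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"variance {se * se:.3g} exceeds Bernoulli bound {mean * (1 - mean):.3g}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given first two moments."""
    if mean <= 0 or se <= 0:
        raise InfeasibleMomentsError("gamma moments must be positive")
    return mean * mean / (se * se), se * se / mean


@lru_cache(maxsize=256)
def truncated_normal_from_moments(
    mean: float, se: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) of a [lo, hi]-truncated normal with the given moments.

    Truncating a normal at its natural bounds shifts its mean and shrinks
    its spread -- severely so for the procedure costs, whose SEs are half
    their means -- so the parent parameters are solved numerically such that
    the *truncated* distribution reproduces the printed mean and SE.  A
    0-truncated normal cannot have a coefficient of variation at or above 1;
    such moments raise :class:`InfeasibleMomentsError`.
    """
    from scipy import optimize

    if se <= 0:
        raise InfeasibleMomentsError("truncated normal needs a positive SE")
    if not lo < mean < hi:
        raise InfeasibleMomentsError("mean must lie inside the truncation bounds")
    if lo == 0.0 and not math.isfinite(hi) and se / mean >= 0.999:
        raise InfeasibleMomentsError(
            "a non-negative truncated normal cannot have CV >= 1"
        )

    def resid(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a = (lo - mu) / sigma
        b = (hi - mu) / sigma if math.isfinite(hi) else math.inf
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - se]

    sol, info, ok, _ = optimize.fsolve(
        resid, [mean, math.log(se)], full_output=True, xtol=1e-12
    )
    if ok != 1 or max(abs(r) for r in info["fvec"]) > 1e-6 * max(se, 1.0):
        raise InfeasibleMomentsError(
            f"no truncated normal on [{lo}, {hi}] matches mean {mean}, se {se}"
        )
    return float(sol[0]), float(math.exp(sol[1]))


# ---------------------------------------------------------------------------
# sampling


def _truncation_bounds(spec: ParameterSpec) -> tuple[float, float]:
    # Natural bounds: costs are non-negative, utilities live in [0, 1].
    if spec.group == "cost":
        return 0.0, math.inf
    return 0.0, 1.0


def _truncnorm_ppf(u: np.ndarray, mean: float, se: float, lo: float, hi: float) -> np.ndarray:
    """Quantiles of a normal(mean, se) truncated to [lo, hi].

    The parent normal carries the printed moments; truncation (and, inside
    an order group, the ordering constraint) shifts the realised moments,
    noticeably so for the procedure costs whose SEs are a large fraction of
    their means.  :func:`truncated_normal_from_moments` quantifies the
    truncation part of that shift.
    """
    if se == 0:
        return np.full_like(u, mean)
    a = (lo - mean) / se
    b = (hi - mean) / se if math.isfinite(hi) else math.inf
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=se)


def sample_ordered_truncated_normal_group(
    specs: Sequence[ParameterSpec],
    rng: np.random.Generator,
    n: int = 1,
    retry_budget: int = ORDERED_GROUP_RETRY_BUDGET,
) -> dict[int, np.ndarray]:
    """Jointly draw a truncated-normal order group.

    Each member is marginally normal(mean, se) truncated to its natural
    bounds (costs >= 0, utilities in [0, 1]).  All members of one joint
    draw share a single quantile (a comonotone draw): a draw that is
    expensive or severe on one member is equally severe on the others.
    This preserves every marginal mean exactly -- whole-group rejection
    would visibly bias marginals whose means sit within a fraction of an SE
    of each other, as the published care costs do -- while the shared
    quantile makes ordering violations rare (the quantile curves cross only
    in remote tails); those rare draws are redrawn until ordered.
    """
    members = sorted(specs, key=lambda s: s.order_rank if s.order_rank is not None else 0)
    if len({s.order_group for s in members}) != 1:
        raise SchemaError("group members must share one order_group")
    means = np.array([s.mean for s in members])
    ascending = bool(means[-1] >= means[0])

    def draw_block(m: int) -> np.ndarray:
        u = rng.uniform(size=m)  # one shared quantile per joint draw
        block = np.empty((m, len(members)))
        for j, s in enumerate(members):
            lo, hi = _truncation_bounds(s)
            block[:, j] = _truncnorm_ppf(u, s.mean, s.se, lo, hi)
        return block

    def violated(block: np.ndarray) -> np.ndarray:
        d = np.diff(block, axis=1)
        return (d < 0).any(axis=1) if ascending else (d > 0).any(axis=1)

    out = draw_block(n)
    bad = violated(out)
    attempts = 0
    while bad.any():
        attempts += 1
        if attempts > retry_budget:
            raise SamplingFailureError(
                f"order group {members[0].order_group!r}: ordering not reached "
                f"after {retry_budget} redraws"
            )
        idx = np.flatnonzero(bad)
        out[idx] = draw_block(len(idx))
        bad[idx] = violated(out[idx])
    return {s.id: out[:, j] for j, s in enumerate(members)}


def sample_draws(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    n: int,
    rng: np.random.Generator,
) -> DrawSet:
    """Draw ``n`` joint parameter realizations (vectorized).

    The untreated-aneurysm disutility (row 22) is drawn as a Beta magnitude
    and returned negative.  The HTI efficacy comes from ``hti``, not from
    row 24 (whose table entry records the base-case family).
    """
    by_id = {s.id: s for s in specs}
    if sorted(by_id) != list(range(1, 26)):
        raise SchemaError("sample_draws needs the complete 25-row table")

    values: dict[int, np.ndarray] = {}
    groups: dict[str, list[ParameterSpec]] = {}
    for s in specs:
        if s.order_group:
            groups.setdefault(s.order_group, []).append(s)
            continue
        if s.id == RRR_ID:
            values[s.id] = np.full(n, s.mean)
        elif s.dist_family == "deterministic" or s.se == 0:
            values[s.id] = np.full(n, s.mean)
        elif s.dist_family == "beta":
            mean = abs(s.mean) if s.id == DISUTILITY_ID else s.mean
            a, b = beta_from_moments(mean, s.se)
            draw = rng.beta(a, b, n)
            values[s.id] = -draw if s.id == DISUTILITY_ID else draw
        elif s.dist_family == "gamma":
            shape, scale = gamma_from_moments(s.mean, s.se)
            values[s.id] = rng.gamma(shape, scale, n)
        elif s.dist_family == "truncated_ordered_normal":
            lo, hi = _truncation_bounds(s)
            values[s.id] = _truncnorm_ppf(rng.uniform(size=n), s.mean, s.se, lo, hi)
        elif s.dist_family == "uniform":
            values[s.id] = rng.uniform(0.0, 1.0, n)
        else:  # pragma: no cover - families are validated upstream
            raise SchemaError(f"row {s.id}: unsupported family {s.dist_family}")

    for members in groups.values():
        values.update(sample_ordered_truncated_normal_group(members, rng, n))

    # Age-band mRS 0 utilities share the row-19 draw via a common offset.
    base19 = by_id[19].mean
    offset = values[19] - base19
    band_means = np.array([m for (_, _, m) in MRS0_UTILITY_BANDS])
    mrs0_bands = np.clip(band_means[None, :] + offset[:, None], 0.0, 1.0)

    rrr = hti.sample(n, rng)
    return DrawSet(values, rrr, mrs0_bands)


def sample_draw(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    rng: np.random.Generator,
) -> ParameterDraw:
    """Draw a single joint parameter realization."""
    return sample_draws(specs, hti, 1, rng).row(0)


# ---------------------------------------------------------------------------
# time-scale conversion


def per_cycle_probability(
    p: float,
    source_duration_years: float,
    cycle_years: float = 0.5,
    method: str = "hazard",
):
    """Rescale a probability quoted over ``source_duration_years`` to one cycle.

    ``method="hazard"`` assumes a constant hazard,
    ``1 - (1-p)**(cycle/source)``; ``method="linear"`` rescales
    proportionally, ``p * cycle/source`` (the convention of many spreadsheet
    cohort models, and the engine's default via
    :attr:`ModelConfig.prob_conversion`).  A source duration of 0 marks a
    per-event/per-procedure probability, which passes through unchanged.
    Accepts scalars or arrays.
    """
    p_arr = np.asarray(p, dtype=float)
    if source_duration_years == 0:
        return p if np.isscalar(p) else p_arr
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise DegenerateProbabilityError("probability outside [0,1]")
    if method == "hazard":
        if source_duration_years != cycle_years and np.any(p_arr == 1.0):
            raise DegenerateProbabilityError(
                "p = 1 has infinite hazard and cannot be rescaled"
            )
        out = -np.expm1(np.log1p(-p_arr) * (cycle_years / source_duration_years))
    elif method == "linear":
        out = np.clip(p_arr * (cycle_years / source_duration_years), 0.0, 1.0)
    else:
        raise ValueError(f"unknown conversion method {method!r}")
    return float(out) if np.isscalar(p) else out


def expected_recanalization_with_hti(p_source: float, expected_rrr: float) -> float:
    """Expected absolute recanalization probability (source time base) under
    the adjunct: ``p * (1 - E[RRR])`` -- e.g. 0.244 * 0.5 = 0.122 per 6 years."""
    return p_source * (1.0 - expected_rrr)
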