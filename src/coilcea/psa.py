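"""Probabilistic sensitivity analysis: Monte Carlo runs and replication.

One PSA iteration draws a joint parameter realization, propagates it through
both strategy arms under common random numbers, and records the discounted
cost and QALY totals.  The headline analysis uses 7,000 iterations; the
whole simulation is replicated 100 times on independent substreams to attach
95% credible intervals (2.5th/97.5th percentiles across replicates) to every
summary statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, PopulationSpec
from .errors import ValidationError
from .markov import evaluate_arms, feasibility_mask
from .parameters import DrawSet, HtiEfficacySpec, ParameterSpec, sample_draws

__all__ = ["PsaSampleSet", "ReplicateSummary", "run_psa", "replicate_psa",
           "convergence_profile", "draw_feasible"]

_MAX_REDRAW_ROUNDS = 100


@dataclass
class PsaSampleSet:
    """Per-iteration discounted outcomes for both arms under common draws."""

    cost_std: np.ndarray
    qaly_std: np.ndarray
    cost_hti: np.ndarray
    qaly_hti: np.ndarray
    rrr: np.ndarray
    draw_values: dict[int, np.ndarray] = field(default_factory=dict)
    seed: Optional[int] = None
    label: str = "base case"
    n_infeasible_redrawn: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.cost_std)

    @property
    def inc_cost(self) -> np.ndarray:
        return self.cost_hti - self.cost_std

    @property
    def inc_qaly(self) -> np.ndarray:
        return self.qaly_hti - self.qaly_std

    def nmb(self, threshold: float) -> np.ndarray:
        """Incremental net monetary benefit at willingness-to-pay ``threshold``."""
        return threshold * self.inc_qaly - self.inc_cost

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "cost_std": self.cost_std,
                "qaly_std": self.qaly_std,
                "cost_hti": self.cost_hti,
                "qaly_hti": self.qaly_hti,
                "rrr": self.rrr,
            }
        )


@dataclass
class ReplicateSummary:
    """Replicate-level statistics with expected values and credible intervals."""

    stats: pd.DataFrame  # one row per replicate
    expected: dict[str, float]
    cri_low: dict[str, float]
    cri_high: dict[str, float]

    def __post_init__(self):
        for k, v in self.expected.items():
            if not (self.cri_low[k] <= v <= self.cri_high[k]) and np.isfinite(v):
                raise ValidationError(f"credible interval of {k!r} excludes its mean")


def draw_feasible(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    n: int,
    rng: np.random.Generator,
) -> tuple[DrawSet, int]:
    """Draw ``n`` realizations, rejecting and redrawing infeasible ones.

    A draw is infeasible when its categorical outcome splits (procedural
    complications, aSAH outcomes) sum above 1; redrawing preserves the
    stated marginals, unlike clipping.  Returns the set and the number of
    redrawn rows.
    """
    ds = sample_draws(specs, hti, n, rng)
    redrawn = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = ~feasibility_mask(ds)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        redrawn += n_bad
        ds.overwrite(bad, sample_draws(specs, hti, n_bad, rng))
    else:  # pragma: no cover - would need pathological inputs
        raise ValidationError("could not draw a feasible parameter set")
    if redrawn > 0.01 * n:
        warnings.warn(
            f"{redrawn} of {n} draws were infeasible and redrawn; "
            "check the parameter table", stacklevel=2
        )
    return ds, redrawn


def run_psa(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    config: ModelConfig,
    n_iterations: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    label: str = "base case",
) -> PsaSampleSet:
    """Run one Monte Carlo PSA of ``n_iterations`` common-random-number draws."""
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    ds, redrawn = draw_feasible(specs, hti, n_iterations, rng)
    out = evaluate_arms(ds, config)
    return PsaSampleSet(
        cost_std=out["cost_std"],
        qaly_std=out["qaly_std"],
        cost_hti=out["cost_hti"],
        qaly_hti=out["qaly_hti"],
        rrr=ds.rrr.copy(),
        draw_values={pid: a.copy() for pid, a in ds.values.items()},
        seed=seed,
        label=label,
        n_infeasible_redrawn=redrawn,
    )


def replicate_psa(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    config: ModelConfig,
    n_iterations: int = 7_000,
    n_replicates: int = 100,
    seed: Optional[int] = None,
    thresholds: Optional[Sequence[float]] = None,
    population: Optional[PopulationSpec] = None,
) -> ReplicateSummary:
    """Repeat the PSA on independent substreams and summarise across replicates.

    Each replicate contributes its per-arm means, ICER, CEAC points, and
    population EVPI; the expected value of each statistic is the replicate
    mean and the credible interval its 2.5th/97.5th percentiles.
    """
    from . import voi  # local import to avoid a module cycle

    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    thresholds = tuple(thresholds if thresholds is not None else config.thresholds)
    population = population or PopulationSpec()

    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for k, ss in enumerate(streams):
        psa = run_psa(
            specs, hti, config, n_iterations,
            rng=np.random.default_rng(ss), label=f"replicate {k}",
        )
        row = {
            "cost_std": float(psa.cost_std.mean()),
            "cost_hti": float(psa.cost_hti.mean()),
            "qaly_std": float(psa.qaly_std.mean()),
            "qaly_hti": float(psa.qaly_hti.mean()),
            "icer": voi.icer(psa),
        }
        for lam in thresholds:
            row[f"ceac_{int(lam)}"] = voi.ceac_point(psa, lam)
            pp = voi.evpi_per_person(psa, lam)
            row[f"evpi_pp_{int(lam)}"] = pp
            row[f"evpi_pop_{int(lam)}"] = voi.scale_to_population(pp, population)
        rows.append(row)

    stats = pd.DataFrame(rows)
    expected = {c: float(stats[c].mean()) for c in stats.columns}
    lo = {c: float(np.percentile(stats[c], 2.5)) for c in stats.columns}
    hi = {c: float(np.percentile(stats[c], 97.5)) for c in stats.columns}
    return ReplicateSummary(stats=stats, expected=expected, cri_low=lo, cri_high=hi)


def convergence_profile(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    config: ModelConfig,
    max_iterations: int = 10_000,
    checkpoints: Optional[Sequence[int]] = None,
    seed: Optional[int] = None,
    stability_tol: float = 0.01,
) -> pd.DataFrame:
    """Running ICER and incremental net benefit at increasing iteration counts.

    A checkpoint is flagged stable once the running ICER changed by less
    than ``stability_tol`` (relative) from the previous checkpoint.
    """
    if checkpoints is None:
        checkpoints = list(range(500, max_iterations + 1, 500))
    checkpoints = list(checkpoints)
    if checkpoints != sorted(checkpoints) or len(set(checkpoints)) != len(checkpoints):
        raise ValidationError("checkpoints must be strictly increasing")
    if checkpoints[-1] > max_iterations:
        raise ValidationError("checkpoint beyond max_iterations")

    psa = run_psa(specs, hti, config, max_iterations, seed=seed)
    lam = config.thresholds[0]
    rows = []
    prev = None
    for n in checkpoints:
        d_c = psa.inc_cost[:n].mean()
        d_e = psa.inc_qaly[:n].mean()
        running_icer = d_c / d_e if d_e != 0 else np.nan
        stable = prev is not None and np.isfinite(running_icer) and abs(
            running_icer - prev
        ) < stability_tol * abs(prev)
        rows.append(
            {
                "iterations": n,
                "icer": running_icer,
                "mean_inb": lam * d_e - d_c,
                "stable": bool(stable),
            }
        )
        prev = running_icer
    return pd.DataFrame(rows)
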