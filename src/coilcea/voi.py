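"""Decision analytics: ICER, CEAC, EVPI/EVPPI, tornado and scenario analyses.

All quantities derive from per-iteration incremental costs and QALYs of the
adjunct (HTI) arm versus standard coiling.  Net monetary benefit at a
willingness-to-pay threshold lambda is ``NMB = lambda * QALY - cost``; the
expected value of perfect information is the expected gain from always
choosing the per-draw best strategy instead of the on-average best one, and
the partial EVPI (EVPPI) restricts the resolved uncertainty to one
parameter via two-level nested Monte Carlo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import ModelConfig, PopulationSpec
from .errors import UndefinedICERError, ValidationError
from .markov import evaluate_arms
from .parameters import HtiEfficacySpec, ParameterSpec
from .psa import PsaSampleSet, draw_feasible, run_psa

__all__ = [
    "CeaSummary", "TornadoEntry", "icer", "ceac_point", "evpi_per_person",
    "scale_to_population", "evppi", "tornado_one_way",
    "discount_rate_scenarios", "scenario_rrr", "cea_summary",
]


@dataclass(frozen=True)
class CeaSummary:
    """Reportable cost-effectiveness summary of one PSA."""

    label: str
    cost_std: float
    cost_hti: float
    qaly_std: float
    qaly_hti: float
    icer: float
    ceac: tuple[tuple[float, float], ...]  # (threshold, P(cost-effective))
    evpi_per_person: tuple[tuple[float, float], ...]
    evpi_population: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    variable_id: int
    name: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def icer(psa: PsaSampleSet) -> float:
    """Ratio of mean incremental cost to mean incremental QALYs (USD/QALY).

    Raises :class:`UndefinedICERError` when the mean incremental QALY is
    zero (identical arms); a costless gain reports 0 (dominant).
    """
    d_e = float(psa.inc_qaly.mean())
    d_c = float(psa.inc_cost.mean())
    if d_e == 0.0:
        raise UndefinedICERError(
            "incremental QALYs are zero; report dominance status instead"
        )
    return d_c / d_e


def ceac_point(psa: PsaSampleSet, threshold: float) -> float:
    """Probability the adjunct is cost-effective at ``threshold`` ($/QALY).

    The fraction of iterations with strictly positive incremental net
    monetary benefit; ties count as not cost-effective.
    """
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    return float((psa.nmb(threshold) > 0).mean())


def evpi_per_person(psa: PsaSampleSet, threshold: float) -> float:
    """Expected value of perfect information per patient (USD).

    ``E[max_s NMB_s] - max_s E[NMB_s]`` over the two strategies; since both
    arms share draws, this is ``E[max(inb, 0)] - max(E[inb], 0)`` with
    ``inb`` the incremental NMB.  Non-negative up to floating error.
    """
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    inb = psa.nmb(threshold)
    return float(np.maximum(inb, 0.0).mean() - max(inb.mean(), 0.0))


def scale_to_population(per_person: float, population: PopulationSpec) -> float:
    """Undiscounted scaling to the treated population (procedures/yr x years)."""
    return per_person * population.size


def evppi(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    config: ModelConfig,
    focal_variable: int,
    n_outer: int = 1_000,
    n_inner: int = 1_000,
    seed: Optional[int] = None,
    thresholds: Optional[Sequence[float]] = None,
    population: Optional[PopulationSpec] = None,
) -> dict[float, dict[str, float]]:
    """Expected value of partially perfect information for one parameter.

    Brute-force two-level nesting: the focal parameter is drawn ``n_outer``
    times; conditional on each outer value, ``n_inner`` fresh draws of all
    other parameters estimate each strategy's expected NMB.  EVPPI per
    person is ``E_outer[max_s E_inner NMB_s] - max_s E[NMB_s]``, floored at
    0.  Returns, per threshold, the per-person and population-scaled values.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValidationError("n_outer and n_inner must be >= 2")
    by_id = {s.id: s for s in specs}
    focal = by_id[focal_variable]
    thresholds = tuple(thresholds if thresholds is not None else config.thresholds)
    population = population or PopulationSpec()

    if focal.dist_family == "deterministic" or focal.se == 0:
        warnings.warn(f"variable {focal_variable} is deterministic; EVPPI is 0",
                      stacklevel=2)
        return {lam: {"per_person": 0.0, "population": 0.0} for lam in thresholds}

    rng = np.random.default_rng(seed)
    outer = draw_feasible(specs, hti, n_outer, rng)[0].values[focal_variable]

    ds, _ = draw_feasible(specs, hti, n_outer * n_inner, rng)
    ds.values[focal_variable][:] = np.repeat(outer, n_inner)
    out = evaluate_arms(ds, config)
    inc_q = (out["qaly_hti"] - out["qaly_std"]).reshape(n_outer, n_inner)
    inc_c = (out["cost_hti"] - out["cost_std"]).reshape(n_outer, n_inner)

    results = {}
    for lam in thresholds:
        inner_mean_inb = (lam * inc_q - inc_c).mean(axis=1)
        overall = inner_mean_inb.mean()
        pp = max(float(np.maximum(inner_mean_inb, 0.0).mean() - max(overall, 0.0)), 0.0)
        results[lam] = {
            "per_person": pp,
            "population": scale_to_population(pp, population),
        }
    return results


def _with_fixed(specs: Sequence[ParameterSpec], pid: int, value: float):
    """Copy of the parameter table with one variable pinned to ``value``."""
    from dataclasses import replace

    out = []
    for s in specs:
        if s.id == pid:
            mean = value
            fam = "deterministic" if s.order_group is None else s.dist_family
            out.append(replace(s, mean=mean, se=0.0, dist_family=fam))
        else:
            out.append(s)
    return out


def tornado_one_way(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    config: ModelConfig,
    n_iterations: int = 2_000,
    seed: Optional[int] = None,
) -> list[TornadoEntry]:
    """Probabilistic one-way sensitivity analysis.

    For every variable with published sensitivity bounds, the full PSA is
    rerun twice with that variable pinned to its lower and upper bound while
    all other parameters stay stochastic; entries are sorted by the spread
    of the two resulting ICERs.  Common seeds keep the comparison paired.
    """
    entries = []
    for s in specs:
        if s.group == "hti" or not np.isfinite(s.sens_low) or not np.isfinite(s.sens_high):
            continue
        icers = []
        for bound in (s.sens_low, s.sens_high):
            mod = _with_fixed(specs, s.id, bound)
            psa = run_psa(mod, hti, config, n_iterations, seed=seed,
                          label=f"tornado v{s.id}")
            icers.append(icer(psa))
        entries.append(
            TornadoEntry(
                variable_id=s.id, name=s.name,
                low_value=s.sens_low, high_value=s.sens_high,
                icer_at_low=icers[0], icer_at_high=icers[1],
            )
        )
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def discount_rate_scenarios(
    specs: Sequence[ParameterSpec],
    hti: HtiEfficacySpec,
    config: ModelConfig,
    rates: Sequence[float] = (0.0, 0.03, 0.05),
    n_iterations: int = 7_000,
    seed: Optional[int] = None,
) -> dict[float, float]:
    """Base-case ICER recomputed under alternative annual discount rates."""
    from dataclasses import replace

    out = {}
    for rate in rates:
        if rate < 0:
            raise ValidationError("discount rates must be non-negative")
        cfg = replace(config, discount_rate=rate)
        psa = run_psa(specs, hti, cfg, n_iterations, seed=seed,
                      label=f"discount {rate:.1%}")
        out[rate] = icer(psa)
    return out


def cea_summary(
    psa: PsaSampleSet,
    thresholds: Sequence[float],
    population: Optional[PopulationSpec] = None,
) -> CeaSummary:
    """Summarise one PSA into the reportable quantities."""
    population = population or PopulationSpec()
    ceac = tuple((lam, ceac_point(psa, lam)) for lam in thresholds)
    evpi_pp = tuple((lam, evpi_per_person(psa, lam)) for lam in thresholds)
    evpi_pop = tuple(
        (lam, scale_to_population(v, population)) for lam, v in evpi_pp
    )
    return CeaSummary(
        label=psa.label,
        cost_std=float(psa.cost_std.mean()),
        cost_hti=float(psa.cost_hti.mean()),
        qaly_std=float(psa.qaly_std.mean()),
        qaly_hti=float(psa.qaly_hti.mean()),
        icer=icer(psa),
        ceac=ceac,
        evpi_per_person=evpi_pp,
        evpi_population=evpi_pop,
    )


def scenario_rrr(
    specs: Sequence[ParameterSpec],
    config: ModelConfig,
    scenarios: Optional[dict[str, HtiEfficacySpec]] = None,
    n_iterations: int = 7_000,
    seed: Optional[int] = None,
    population: Optional[PopulationSpec] = None,
) -> dict[str, CeaSummary]:
    """Scenario analyses over alternative adjunct-efficacy distributions.

    The defaults are bounded normals with mean (SD) of 10% (2%), 30% (5%)
    and 50% (15%); the adjunct price stays at its base-case value.
    """
    if scenarios is None:
        scenarios = {
            "10 (2)": HtiEfficacySpec("bounded_normal", mu=0.10, sigma=0.02),
            "30 (5)": HtiEfficacySpec("bounded_normal", mu=0.30, sigma=0.05),
            "50 (15)": HtiEfficacySpec("bounded_normal", mu=0.50, sigma=0.15),
        }
    out = {}
    for label, eff in scenarios.items():
        psa = run_psa(specs, eff, config, n_iterations, seed=seed, label=label)
        out[label] = cea_summary(psa, config.thresholds, population)
    return out
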