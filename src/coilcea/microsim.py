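"""Individual-level microsimulation oracle and synthetic parameter tables.

The microsimulation steps single patients through the same state dynamics
as the cohort engine -- identical per-cycle probabilities, accrual rules and
discounting -- but with its own event-sampling loop and its own competing-
risk arithmetic, sharing no propagation code with the cohort path.  Cohort
and microsimulation means must agree within Monte Carlo error; a bug in
either engine would have to be made twice, identically, to escape the
comparison.

The module also generates random but valid parameter tables with the same
structure as the published one (families, groups, orderings), so every
pipeline stage can be property-tested without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import STRATEGY_HTI, STRATEGY_STANDARD, ModelConfig
from .errors import InfeasibleDrawError, ValidationError
from .markov import ArmOutcome, discount_factor, run_cohort
from .parameters import (
    MRS0_UTILITY_BANDS,
    HtiEfficacySpec,
    ParameterDraw,
    ParameterSpec,
    per_cycle_probability,
)
from .states import KIND_ASAH, KIND_COILED, KIND_DEAD, KIND_UNSECURED, StateSpace, Status, worst

__all__ = [
    "MicrosimResult", "PatientPath", "simulate_patients",
    "cohort_vs_microsim_check", "CheckReport", "random_parameter_table",
]


@dataclass(frozen=True)
class MicrosimResult:
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n_patients: int


@dataclass
class PatientPath:
    """Cycle-by-cycle state labels for one simulated patient (debug aid)."""

    states: list[str]
    cost: float
    qaly: float


def _hazard_split(probs: list[float]) -> tuple[list[float], float]:
    """Competing-risk allocation, written independently of the cohort engine.

    Converts each per-cycle probability to a hazard, shares the combined
    event probability proportionally, and returns the exact survivor mass.
    """
    hazards = [-math.log1p(-p) if p < 1.0 else math.inf for p in probs]
    total = sum(hazards)
    if total == 0.0:
        return [0.0] * len(probs), 1.0
    stay = math.exp(-total)
    p_any = 1.0 - stay
    return [p_any * h / total for h in hazards], stay


class _EventTables:
    """Per-state outcome distributions for one mortality/window regime."""

    def __init__(self, draw: ParameterDraw, config: ModelConfig, strategy: str,
                 q: float, recan_active: bool):
        v = draw.values
        cy = config.cycle_years
        conv = config.prob_conversion
        sp = StateSpace(config.max_procedures)
        self.sp = sp

        p_recan = per_cycle_probability(v[4], 6.0, cy, conv)
        if config.retreat_conditional:
            p_retreat = per_cycle_probability(
                min(max(v[5] / max(v[4], 1e-12), 0.0), 1.0 - 1e-12), 6.0, cy, conv)
        else:
            p_retreat = per_cycle_probability(v[5], 6.0, cy, conv)
        p_denovo = per_cycle_probability(v[6], 1.0, cy, conv)
        p_rupture = per_cycle_probability(v[7], 1.0, cy, conv)
        p1, p2, p3 = v[1], v[2], v[3]
        resid_proc = 1.0 - p1 - p2 - p3
        d8, d9, d10, d11 = v[8], v[9], v[10], v[11]
        resid_asah = 1.0 - d9 - d10 - d11
        if resid_proc < 0 or resid_asah < 0:
            raise InfeasibleDrawError("outcome split probabilities sum above 1")
        c12, c13, c14, c18 = v[12], v[13], v[14], v[18]

        # state index -> (cumulative outcome probabilities, destinations, costs)
        self.table: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for i in range(1, sp.max_procedures + 1):
            p_rec_i = p_recan
            if strategy == STRATEGY_HTI and i == 1:
                p_rec_i = p_recan * (1.0 - draw.rrr)
            if not recan_active:
                p_rec_i = 0.0
            for s in (Status.MRS0, Status.MRS1_2, Status.MRS3_5):
                (a_rec, a_nov, a_q), stay = _hazard_split([p_rec_i, p_denovo, q])
                self._add(sp.coiled(i, s), [
                    (a_rec + a_nov, sp.unsecured(i, s), 0.0),
                    (a_q, sp.dead, 0.0),
                    (stay, sp.coiled(i, s), 0.0),
                ])

                p_ret = p_retreat if i < sp.max_procedures else 0.0
                (a_rup, a_ret, a_q2), stay2 = _hazard_split([p_rupture, p_ret, q])
                outcomes = [
                    (a_rup * d8, sp.dead, 0.0),
                    (a_rup * (1.0 - d8), sp.asah(i, s), c18),
                    (a_q2, sp.dead, 0.0),
                    (stay2, sp.unsecured(i, s), 0.0),
                ]
                if i < sp.max_procedures:
                    outcomes += [
                        (a_ret * resid_proc, sp.coiled(i + 1, s), c12),
                        (a_ret * p1, sp.coiled(i + 1, worst(s, Status.MRS1_2)), c13),
                        (a_ret * p2, sp.coiled(i + 1, worst(s, Status.MRS3_5)), c13),
                        (a_ret * p3, sp.dead, c14),
                    ]
                self._add(sp.unsecured(i, s), outcomes)

                j = min(i + 1, sp.max_procedures)
                self._add(sp.asah(i, s), [
                    (d9, sp.dead, 0.0),
                    (d10, sp.coiled(j, worst(s, Status.MRS1_2)), 0.0),
                    (d11, sp.coiled(j, worst(s, Status.MRS3_5)), 0.0),
                    (resid_asah, sp.coiled(j, s), 0.0),
                ])
        self._add(sp.dead, [(1.0, sp.dead, 0.0)])

    def _add(self, state: int, outcomes):
        probs = np.array([o[0] for o in outcomes])
        dests = np.array([o[1] for o in outcomes], dtype=np.int64)
        costs = np.array([o[2] for o in outcomes])
        self.table[state] = (np.cumsum(probs), dests, costs)


def _accrual_vectors(draw: ParameterDraw, config: ModelConfig, band: int):
    """Per-cycle QALY and care-cost accrual per state (matches the cohort rules)."""
    sp = StateSpace(config.max_procedures)
    cy = config.cycle_years
    v = draw.values
    u_by_status = [draw.mrs0_by_band[band], v[20], v[21]]
    care = [v[15], v[16], v[17]]
    U = np.zeros(sp.n)
    C = np.zeros(sp.n)
    for i in range(1, sp.max_procedures + 1):
        for s in (Status.MRS0, Status.MRS1_2, Status.MRS3_5):
            U[sp.coiled(i, s)] = u_by_status[int(s)] * cy
            C[sp.coiled(i, s)] = care[int(s)] * cy
            U[sp.unsecured(i, s)] = (u_by_status[int(s)] + v[22]) * cy
            C[sp.unsecured(i, s)] = care[int(s)] * cy
            U[sp.asah(i, s)] = v[23] * cy
    return U, C


def _band_index(age: float) -> int:
    for k, (lo, hi, _) in enumerate(MRS0_UTILITY_BANDS):
        if lo <= age < hi:
            return k
    return len(MRS0_UTILITY_BANDS) - 1


def simulate_patients(
    draw: ParameterDraw,
    config: ModelConfig,
    strategy: str,
    n_patients: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    collect_paths: bool = False,
) -> MicrosimResult | tuple[MicrosimResult, list[PatientPath]]:
    """Simulate individual patients through the model for one draw and arm."""
    if strategy not in (STRATEGY_STANDARD, STRATEGY_HTI):
        raise ValidationError(f"unknown strategy {strategy!r}")
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    v = draw.values
    sp = StateSpace(config.max_procedures)
    nc = config.n_cycles
    n = n_patients

    cost = np.zeros(n)
    qaly = np.zeros(n)

    # index procedure: complication split, procedure cost, adjunct price
    p1, p2, p3 = v[1], v[2], v[3]
    u = rng.random(n)
    state = np.full(n, sp.coiled(1, Status.MRS0), dtype=np.int64)
    cost += v[12]
    sel = u < p1 + p2 + p3
    state[u < p1 + p2 + p3] = sp.coiled(1, Status.MRS1_2)
    state[u < p2 + p3] = sp.coiled(1, Status.MRS3_5)
    state[u < p3] = sp.dead
    cost[sel] += v[13] - v[12]
    cost[u < p3] += v[14] - v[13]
    if strategy == STRATEGY_HTI:
        cost += config.hti_price

    paths = [PatientPath([sp.states[s].label], 0.0, 0.0) for s in state] if collect_paths else None

    tables = None
    regime = None
    Uvec = Cvec = None
    band_seen = None
    from .markov import _per_cycle_mortality, _recan_active

    for c in range(nc):
        df = discount_factor(c, config.discount_rate, config.cycle_years)
        q = _per_cycle_mortality(config, c)
        active = _recan_active(config, c)
        band = _band_index(config.age_at_cycle(c))
        if (q, active) != regime:
            tables = _EventTables(draw, config, strategy, q, active)
            regime = (q, active)
        if band != band_seen:
            Uvec, Cvec = _accrual_vectors(draw, config, band)
            band_seen = band

        qaly += df * Uvec[state]
        cost += df * Cvec[state]

        nxt = state.copy()
        u = rng.random(n)
        for s_idx, (cum, dests, costs) in tables.table.items():
            idx = np.flatnonzero(state == s_idx)
            if len(idx) == 0:
                continue
            k = np.searchsorted(cum, u[idx], side="right")
            k = np.minimum(k, len(dests) - 1)
            nxt[idx] = dests[k]
            cost[idx] += df * costs[k]
        state = nxt
        if collect_paths:
            for p, s in zip(paths, state):
                p.states.append(sp.states[s].label)

    result = MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        n_patients=n,
    )
    if collect_paths:
        for p, ci, qi in zip(paths, cost, qaly):
            p.cost, p.qaly = float(ci), float(qi)
        return result, paths
    return result


@dataclass(frozen=True)
class CheckReport:
    """Cohort-versus-microsimulation agreement report."""

    passed: bool
    details: tuple[tuple[str, float, float, float], ...]  # (metric, cohort, microsim, z)

    def __str__(self) -> str:
        lines = [f"{'PASS' if self.passed else 'FAIL'} cohort vs microsimulation"]
        for name, coh, mic, z in self.details:
            lines.append(f"  {name}: cohort={coh:.4f} microsim={mic:.4f} z={z:.2f}")
        return "\n".join(lines)


def cohort_vs_microsim_check(
    draw: ParameterDraw,
    config: ModelConfig,
    n_patients: int = 20_000,
    tolerance_in_se: float = 3.0,
    seed: Optional[int] = None,
) -> CheckReport:
    """Compare cohort and microsimulation means for both arms.

    Fails if any of the four (arm, metric) deviations exceeds
    ``tolerance_in_se`` Monte Carlo standard errors.
    """
    rng = np.random.default_rng(seed)
    details = []
    passed = True
    for strategy in (STRATEGY_STANDARD, STRATEGY_HTI):
        _, outcome = run_cohort(draw, config, strategy)
        micro = simulate_patients(draw, config, strategy, n_patients, rng=rng)
        for metric, coh, mic, se in (
            ("cost", outcome.discounted_cost, micro.mean_cost, micro.se_cost),
            ("qaly", outcome.discounted_qaly, micro.mean_qaly, micro.se_qaly),
        ):
            z = (mic - coh) / se if se > 0 else 0.0
            details.append((f"{strategy}:{metric}", coh, mic, z))
            if abs(z) > tolerance_in_se:
                passed = False
    return CheckReport(passed=passed, details=tuple(details))


# ---------------------------------------------------------------------------
# synthetic parameter tables


def random_parameter_table(
    rng: np.random.Generator, spread: float = 0.4
) -> list[ParameterSpec]:
    """A random, valid parameter table with the published table's structure.

    Means are jittered multiplicatively (within ``1 +/- spread``), SEs are
    redrawn within moment-feasible ranges, order-group means stay ordered,
    and categorical splits stay below 1, so the result always loads and
    always yields feasible draws.
    """
    from .parameters import default_parameter_table

    base = default_parameter_table()
    out = []

    def jitter(m):
        return m * float(rng.uniform(1.0 - spread, 1.0 + spread))

    mean_by_id: dict[int, float] = {}
    se_by_id: dict[int, float] = {}
    for s in base:
        if s.group == "probability":
            m = min(jitter(s.mean), 0.95)
            se = min(0.25 * m, float(rng.uniform(0.3, 1.5)) * s.se)
            se = min(se, 0.9 * math.sqrt(m * (1 - m)))
        elif s.id == 22:
            mag = min(jitter(abs(s.mean)), 0.3)
            m = -mag
            se = 0.5 * mag
        elif s.group == "cost":
            m = jitter(s.mean)
            se = float(rng.uniform(0.05, 0.5)) * m
        elif s.group == "utility":
            m = float(np.clip(jitter(s.mean), 0.05, 0.98))
            se = float(rng.uniform(0.005, 0.05))
        else:  # hti rows
            m, se = s.mean, s.se
        mean_by_id[s.id] = m
        se_by_id[s.id] = se

    # keep the categorical splits valid with room to spare
    for ids in ((1, 2, 3), (9, 10, 11)):
        total = sum(mean_by_id[i] for i in ids)
        if total > 0.9:
            for i in ids:
                mean_by_id[i] *= 0.9 / total
    # keep retreatment no more frequent than recanalization
    if mean_by_id[5] > mean_by_id[4]:
        mean_by_id[5] = 0.8 * mean_by_id[4]
    # order-group means must preserve their published ordering
    for ids, descending in (((12, 13, 14), False), ((15, 16, 17), False),
                            ((19, 20, 21), True)):
        vals = sorted((mean_by_id[i] for i in ids), reverse=descending)
        for i, vv in zip(ids, vals):
            mean_by_id[i] = vv

    from dataclasses import replace

    for s in base:
        m, se = mean_by_id[s.id], se_by_id[s.id]
        low, high = (m - 2 * se, m + 2 * se)
        if s.group == "probability":
            low, high = max(low, 0.0), min(high, 1.0)
        elif s.group == "cost":
            low = max(low, 0.0)
        elif s.group == "utility" and s.id != 22:
            low, high = max(low, 0.0), min(high, 1.0)
        if s.id == 22:
            low, high = 0.0, m - 2 * se  # magnitude bounds, negative scale
        out.append(replace(s, mean=m, se=se, sens_low=low, sens_high=high))
    return out
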