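"""Markov cohort engine: transition matrices, propagation, accrual.

The cohort enters at age 45 immediately after an index coiling procedure and
is propagated for 60 six-month cycles (30 years).  Two strategies share one
parameter draw (common random numbers): standard coiling, and standard
coiling plus an index-procedure adjunct that multiplies the per-cycle
recanalization probability by ``1 - RRR`` while the index coil (i = 1) is
the most recent procedure.

Structural rules
----------------
* Period-quoted probabilities are rescaled to the half-year cycle by the
  configured convention (proportional by default; constant-hazard optional).
* Recanalization risk is active only inside the surveillance window over
  which its cumulative probability was counted (default 5.5 years of model
  time); de novo aneurysm risk runs for the whole horizon.  De novo
  aneurysms are pooled with recanalization into the *unsecured* state and
  share its rupture/retreatment dynamics.
* Unsecured patients may rupture (aSAH) or be retreated -- by default at the
  6-year retreatment probability conditional on recanalization (the
  published marginal retreatment and recanalization probabilities imply
  that ~37% of recanalized aneurysms are retreated); after the fourth
  procedure no further retreatment is offered and the aneurysm stays
  unsecured.
* A rupture kills a fraction before hospital; admitted patients spend one
  cycle in a tunnel state (aSAH utility, hospital cost) and then die or are
  retreated with functional status ratcheted to the worse of the prior
  status and the aSAH outcome.
* Competing per-cycle events are resolved by converting each probability to
  a hazard, allocating the combined event probability proportionally, and
  leaving the exact survivor fraction in place -- residuals can never go
  negative.
* Background (all-cause) mortality from an abridged life table competes in
  every alive non-tunnel state; it can be switched off.
* No half-cycle correction: costs and QALYs accrue at cycle start with that
  cycle's discount factor; transition-attached costs (retreatment
  procedures, aSAH admissions) are charged in the cycle the transition
  occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import STRATEGY_HTI, STRATEGY_STANDARD, ModelConfig
from .errors import InfeasibleDrawError, ValidationError
from .parameters import DrawSet, ParameterDraw, per_cycle_probability
from .states import STATUSES, StateSpace, Status, worst

__all__ = [
    "ArmOutcome",
    "CohortTrace",
    "discount_factor",
    "age_band_utility",
    "build_transition_matrix",
    "run_cohort",
    "evaluate_arms",
    "feasibility_mask",
]


@dataclass(frozen=True)
class ArmOutcome:
    """Per-strategy totals for one draw (USD, QALYs)."""

    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float


@dataclass
class CohortTrace:
    """Cycle-by-cycle occupancy and event tallies for one draw/strategy."""

    occupancy: np.ndarray  # (n_cycles+1, n_states)
    retreatments: np.ndarray  # flow of retreatment procedures per cycle
    ruptures: np.ndarray  # aSAH events per cycle (incl. pre-hospital deaths)
    asah_admissions: np.ndarray  # tunnel entries per cycle
    state_space: StateSpace


def discount_factor(cycle: int, rate: float, cycle_years: float = 0.5) -> float:
    """``(1 + rate)^(-cycle * cycle_years)``; cycle 0 maps to 1."""
    if rate < 0:
        raise ValidationError("discount rate must be non-negative")
    return float((1.0 + rate) ** (-(cycle * cycle_years)))


def age_band_utility(age: float, draw: ParameterDraw) -> float:
    """The draw's mRS 0 utility for the (half-open) age band containing ``age``."""
    return draw.mrs0_utility(age)


# ---------------------------------------------------------------------------
# vectorized internals


class _Rates:
    """Per-draw per-cycle event probabilities and payoffs (arrays of shape (n,))."""

    def __init__(self, ds: DrawSet, config: ModelConfig):
        v = ds.values
        cy = config.cycle_years
        conv = config.prob_conversion
        self.p_mild = v[1]
        self.p_msev = v[2]
        self.p_pdeath = v[3]
        self.resid_proc = 1.0 - v[1] - v[2] - v[3]
        self.p_recan = per_cycle_probability(v[4], 6.0, cy, conv)
        if config.retreat_conditional:
            # 6-year retreatment probability among the recanalized
            ratio = np.clip(v[5] / np.maximum(v[4], 1e-12), 0.0, 1.0 - 1e-12)
            self.p_retreat = per_cycle_probability(ratio, 6.0, cy, conv)
        else:
            self.p_retreat = per_cycle_probability(v[5], 6.0, cy, conv)
        self.p_denovo = per_cycle_probability(v[6], 1.0, cy, conv)
        self.p_rupture = per_cycle_probability(v[7], 1.0, cy, conv)
        self.d_prehosp = v[8]
        self.d_inhosp = v[9]
        self.a_mild = v[10]
        self.a_msev = v[11]
        self.resid_asah = 1.0 - v[9] - v[10] - v[11]
        self.c_proc = np.stack([v[12], v[13], v[14]])  # by outcome band
        self.c_care = np.stack([v[15], v[16], v[17]])  # annual, by status
        self.c_asah = v[18]
        self.u_mrs12 = v[20]
        self.u_mrs35 = v[21]
        self.d_unsec = v[22]  # negative
        self.u_asah = v[23]
        self.rrr = ds.rrr
        self.mrs0_bands = ds.mrs0_bands
        # expected procedure cost of a retreatment, by complication outcome
        self.e_proc_cost = (
            self.resid_proc * v[12] + (v[1] + v[2]) * v[13] + v[3] * v[14]
        )
        self.n = ds.n

    def check_feasible(self) -> None:
        bad = (self.resid_proc < 0) | (self.resid_asah < 0)
        if bad.any():
            raise InfeasibleDrawError(
                f"{int(bad.sum())} draw(s) have complication or aSAH outcome "
                "probabilities summing above 1"
            )


def feasibility_mask(ds: DrawSet) -> np.ndarray:
    """True where a draw's categorical splits are valid distributions."""
    v = ds.values
    return ((v[1] + v[2] + v[3]) <= 1.0) & ((v[9] + v[10] + v[11]) <= 1.0)


def _allocate(*probs: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Proportional-hazards allocation of competing per-cycle probabilities.

    Returns the allocated probability of each event plus the survivor
    (stay-in-state) fraction ``exp(-sum of hazards)``, which is exact and
    non-negative by construction.
    """
    hazards = [-np.log1p(-np.asarray(p, dtype=float)) for p in probs]
    total = np.sum(hazards, axis=0)
    stay = np.exp(-total)
    p_any = -np.expm1(-total)
    with np.errstate(invalid="ignore", divide="ignore"):
        alloc = [np.where(total > 0, p_any * h / np.where(total > 0, total, 1.0), 0.0)
                 for h in hazards]
    return alloc, stay


def _per_cycle_mortality(config: ModelConfig, cycle: int) -> float:
    q_annual = config.annual_background_mortality(config.age_at_cycle(cycle))
    return float(
        per_cycle_probability(q_annual, 1.0, config.cycle_years, config.prob_conversion)
    )


def _recan_active(config: ModelConfig, cycle: int) -> bool:
    """Recanalization risk applies while model time is inside the
    surveillance window over which the cumulative probability was counted."""
    if config.recan_window_years is None:
        return True
    return cycle * config.cycle_years < config.recan_window_years


def _utility_band_index(age: float) -> int:
    from .parameters import MRS0_UTILITY_BANDS

    for k, (lo, hi, _) in enumerate(MRS0_UTILITY_BANDS):
        if lo <= age < hi:
            return k
    return len(MRS0_UTILITY_BANDS) - 1


def _build_matrices(
    rates: _Rates,
    sp: StateSpace,
    config: ModelConfig,
    strategy: str,
    q: float,
    recan_active: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Transition tensor (n, S, S) and cost-rate matrix (n, S) for one
    mortality regime ``q`` (per-cycle background death probability)."""
    n, S = rates.n, sp.n
    T = np.zeros((n, S, S))
    C = np.zeros((n, S))
    dead = sp.dead
    cy = config.cycle_years
    qv = np.full(n, q)

    for i in range(1, sp.max_procedures + 1):
        hti_active = strategy == STRATEGY_HTI and i == 1
        p_rec = rates.p_recan * (1.0 - rates.rrr) if hti_active else rates.p_recan
        if not recan_active:
            p_rec = np.zeros(n)
        for s in STATUSES:
            # --- coiled(i, s): recanalization / de novo -> unsecured; death
            cs = sp.coiled(i, s)
            (a_rec, a_nov, a_q), stay = _allocate(p_rec, rates.p_denovo, qv)
            T[:, cs, sp.unsecured(i, s)] = a_rec + a_nov
            T[:, cs, dead] += a_q
            T[:, cs, cs] += stay
            C[:, cs] = rates.c_care[int(s)] * cy

            # --- unsecured(i, s): rupture / retreatment / death
            us = sp.unsecured(i, s)
            p_ret = rates.p_retreat if i < sp.max_procedures else np.zeros(n)
            (a_rup, a_ret, a_q2), stay2 = _allocate(rates.p_rupture, p_ret, qv)
            T[:, us, dead] += a_q2 + a_rup * rates.d_prehosp + a_ret * rates.p_pdeath
            T[:, us, sp.asah(i, s)] += a_rup * (1.0 - rates.d_prehosp)
            if i < sp.max_procedures:
                T[:, us, sp.coiled(i + 1, worst(s, Status.MRS0))] += a_ret * rates.resid_proc
                T[:, us, sp.coiled(i + 1, worst(s, Status.MRS1_2))] += a_ret * rates.p_mild
                T[:, us, sp.coiled(i + 1, worst(s, Status.MRS3_5))] += a_ret * rates.p_msev
            T[:, us, us] += stay2
            C[:, us] = (
                rates.c_care[int(s)] * cy
                + a_ret * rates.e_proc_cost
                + a_rup * (1.0 - rates.d_prehosp) * rates.c_asah
            )

            # --- aSAH tunnel: resolves fully within one cycle
            ts = sp.asah(i, s)
            j = min(i + 1, sp.max_procedures)
            T[:, ts, dead] += rates.d_inhosp
            T[:, ts, sp.coiled(j, worst(s, Status.MRS0))] += rates.resid_asah
            T[:, ts, sp.coiled(j, worst(s, Status.MRS1_2))] += rates.a_mild
            T[:, ts, sp.coiled(j, worst(s, Status.MRS3_5))] += rates.a_msev

    T[:, dead, dead] = 1.0
    return T, C


def _qaly_rates(rates: _Rates, sp: StateSpace, config: ModelConfig, band: int) -> np.ndarray:
    """Per-cycle QALY accrual per state, (n, S), for one mRS 0 age band."""
    n, S = rates.n, sp.n
    U = np.zeros((n, S))
    cy = config.cycle_years
    u_by_status = [rates.mrs0_bands[:, band], rates.u_mrs12, rates.u_mrs35]
    for i in range(1, sp.max_procedures + 1):
        for s in STATUSES:
            u = u_by_status[int(s)]
            U[:, sp.coiled(i, s)] = u * cy
            U[:, sp.unsecured(i, s)] = (u + rates.d_unsec) * cy
            U[:, sp.asah(i, s)] = rates.u_asah * cy
    return U


def _initial_state(rates: _Rates, sp: StateSpace, strategy: str, config: ModelConfig):
    """Cycle-0 occupancy after the index procedure, plus the index cost."""
    n = rates.n
    occ = np.zeros((n, sp.n))
    occ[:, sp.coiled(1, Status.MRS0)] = rates.resid_proc
    occ[:, sp.coiled(1, Status.MRS1_2)] = rates.p_mild
    occ[:, sp.coiled(1, Status.MRS3_5)] = rates.p_msev
    occ[:, sp.dead] = rates.p_pdeath
    cost0 = rates.e_proc_cost.copy()
    if strategy == STRATEGY_HTI:
        cost0 += config.hti_price
    return occ, cost0


def _evaluate(
    ds: DrawSet, config: ModelConfig, strategy: str, collect_trace: bool = False
):
    """Propagate all draws in ``ds`` through one strategy arm."""
    if strategy not in (STRATEGY_STANDARD, STRATEGY_HTI):
        raise ValidationError(f"unknown strategy {strategy!r}")
    rates = _Rates(ds, config)
    rates.check_feasible()
    sp = StateSpace(config.max_procedures)
    n, nc = ds.n, config.n_cycles

    df = np.array([discount_factor(c, config.discount_rate, config.cycle_years)
                   for c in range(nc)])
    occ, cost0 = _initial_state(rates, sp, strategy, config)

    disc_cost = cost0.copy()  # index procedure at cycle 0, factor 1
    undisc_cost = cost0.copy()
    disc_qaly = np.zeros(n)
    undisc_qaly = np.zeros(n)

    trace = None
    if collect_trace:
        trace = CohortTrace(
            occupancy=np.zeros((nc + 1, sp.n)),
            retreatments=np.zeros(nc),
            ruptures=np.zeros(nc),
            asah_admissions=np.zeros(nc),
            state_space=sp,
        )
        trace.occupancy[0] = occ[0]

    T = C = U = None
    last_key = None
    last_band = None
    unsec_idx = np.array(
        [sp.unsecured(i, s) for i in range(1, sp.max_procedures + 1) for s in STATUSES]
    )
    for c in range(nc):
        q = _per_cycle_mortality(config, c)
        band = _utility_band_index(config.age_at_cycle(c))
        active = _recan_active(config, c)
        if (q, active) != last_key:
            T, C = _build_matrices(rates, sp, config, strategy, q, active)
            last_key = (q, active)
        if band != last_band:
            U = _qaly_rates(rates, sp, config, band)
            last_band = band

        disc_cost += df[c] * np.einsum("ns,ns->n", occ, C)
        undisc_cost += np.einsum("ns,ns->n", occ, C)
        disc_qaly += df[c] * np.einsum("ns,ns->n", occ, U)
        undisc_qaly += np.einsum("ns,ns->n", occ, U)

        if collect_trace:
            qv = np.full(n, q)
            (a_rup, a_ret, _), _ = _allocate(rates.p_rupture, rates.p_retreat, qv)
            (a_rup4, _), _ = _allocate(rates.p_rupture, qv)
            unsec_occ = occ[0, unsec_idx]
            occ_lt_max = unsec_occ[: 3 * (sp.max_procedures - 1)].sum()
            occ_at_max = unsec_occ[3 * (sp.max_procedures - 1):].sum()
            ruptures = occ_lt_max * a_rup[0] + occ_at_max * a_rup4[0]
            trace.retreatments[c] = occ_lt_max * a_ret[0]
            trace.ruptures[c] = ruptures
            trace.asah_admissions[c] = ruptures * (1.0 - rates.d_prehosp[0])

        occ = np.einsum("ns,nst->nt", occ, T)
        if collect_trace:
            trace.occupancy[c + 1] = occ[0]

    return disc_cost, disc_qaly, undisc_cost, undisc_qaly, trace


# ---------------------------------------------------------------------------
# public API


def build_transition_matrix(
    draw: ParameterDraw, config: ModelConfig, cycle: int, strategy: str
) -> np.ndarray:
    """Per-cycle stochastic matrix over the enumerated states for one draw."""
    if not 0 <= cycle < config.n_cycles:
        raise ValidationError(f"cycle {cycle} outside [0, {config.n_cycles})")
    ds = DrawSet.from_draw(draw)
    rates = _Rates(ds, config)
    rates.check_feasible()
    sp = StateSpace(config.max_procedures)
    q = _per_cycle_mortality(config, cycle)
    T, _ = _build_matrices(rates, sp, config, strategy, q, _recan_active(config, cycle))
    return T[0]


def run_cohort(
    draw: ParameterDraw, config: ModelConfig, strategy: str
) -> tuple[CohortTrace, ArmOutcome]:
    """Propagate a unit cohort for one draw and strategy."""
    ds = DrawSet.from_draw(draw)
    dc, dq, uc, uq, trace = _evaluate(ds, config, strategy, collect_trace=True)
    return trace, ArmOutcome(float(dc[0]), float(dq[0]), float(uc[0]), float(uq[0]))


def evaluate_arms(
    ds: DrawSet, config: ModelConfig, chunk_size: int = 2_000
) -> dict[str, np.ndarray]:
    """Discounted (cost, QALY) for both strategy arms under common draws.

    Draws are processed in chunks to bound the transition-tensor memory.
    Returns arrays ``cost_std, qaly_std, cost_hti, qaly_hti`` of shape (n,).
    """
    out = {k: np.empty(ds.n) for k in ("cost_std", "qaly_std", "cost_hti", "qaly_hti")}
    for lo in range(0, ds.n, chunk_size):
        hi = min(lo + chunk_size, ds.n)
        sub = DrawSet(
            {pid: a[lo:hi] for pid, a in ds.values.items()},
            ds.rrr[lo:hi],
            ds.mrs0_bands[lo:hi],
        )
        cs, qs, _, _, _ = _evaluate(sub, config, STRATEGY_STANDARD)
        ch, qh, _, _, _ = _evaluate(sub, config, STRATEGY_HTI)
        out["cost_std"][lo:hi] = cs
        out["qaly_std"][lo:hi] = qs
        out["cost_hti"][lo:hi] = ch
        out["qaly_hti"][lo:hi] = qh
    return out
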