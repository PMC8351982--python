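"""Health-state space of the coiled-aneurysm Markov model.

A patient who has undergone ``i`` coiling procedures (1-4) is either *coiled*
(aneurysm secured) or *unsecured* (a recanalized or de novo aneurysm is
present and untreated), carries a functional status on the modified Rankin
Scale (mRS 0, mRS 1-2, or mRS 3-5), and may pass through a one-cycle aSAH
*tunnel* state (hospitalised aneurysm rupture) before being retreated.  Death
is the single absorbing state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional


class Status(IntEnum):
    """Functional status; ordering reflects severity (larger = worse)."""

    MRS0 = 0
    MRS1_2 = 1
    MRS3_5 = 2


STATUSES = (Status.MRS0, Status.MRS1_2, Status.MRS3_5)

KIND_COILED = "coiled"
KIND_UNSECURED = "unsecured"
KIND_ASAH = "asah"
KIND_DEAD = "dead"


@dataclass(frozen=True)
class HealthState:
    kind: str
    procedures: Optional[int] = None  # 1..max_procedures; None for dead
    status: Optional[Status] = None  # None for dead
    asah_this_cycle: bool = False

    def __post_init__(self):
        if self.kind == KIND_DEAD:
            if self.status is not None or self.procedures is not None:
                raise ValueError("dead state carries no status or count")
        else:
            if self.procedures is None or self.status is None:
                raise ValueError(f"{self.kind} state needs procedures and status")

    @property
    def label(self) -> str:
        if self.kind == KIND_DEAD:
            return "dead"
        return f"{self.kind}({self.procedures},{self.status.name})"


def worst(a: Status, b: Status) -> Status:
    """Functional status is ratcheted: it can only worsen."""
    return Status(max(int(a), int(b)))


def enumerate_states(max_procedures: int = 4) -> list[HealthState]:
    """Deterministic state ordering: coiled, unsecured, aSAH tunnels, dead.

    With the default four-procedure cap this yields 4*3*2 + 12 + 1 = 37
    states.  The ordering is stable across runs and is relied on by the
    transition-matrix builder and the microsimulation.
    """
    states: list[HealthState] = []
    for kind in (KIND_COILED, KIND_UNSECURED):
        for i in range(1, max_procedures + 1):
            for s in STATUSES:
                states.append(HealthState(kind, i, s))
    for i in range(1, max_procedures + 1):
        for s in STATUSES:
            states.append(HealthState(KIND_ASAH, i, s, asah_this_cycle=True))
    states.append(HealthState(KIND_DEAD))
    return states


class StateSpace:
    """Enumerated states with index lookups used throughout the engine."""

    def __init__(self, max_procedures: int = 4):
        self.max_procedures = max_procedures
        self.states = enumerate_states(max_procedures)
        self.index = {s.label: k for k, s in enumerate(self.states)}
        self.n = len(self.states)
        self.dead = self.n - 1

    def coiled(self, i: int, s: Status) -> int:
        return self.index[f"coiled({i},{s.name})"]

    def unsecured(self, i: int, s: Status) -> int:
        return self.index[f"unsecured({i},{s.name})"]

    def asah(self, i: int, s: Status) -> int:
        return self.index[f"asah({i},{s.name})"]

    def __len__(self) -> int:
        return self.n
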