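"""Injured-worker agents and their entry-attribute distributions.

Workers enter the scheme with individual qualities: health, trust,
satisfaction and an appetite for fighting unfavourable decisions, all
on 100-point scales; a responsiveness-to-treatment multiplier in
[-1, +1]; an expectation of how long claim processing should take; an
injury type (acute physical, chronic physical or mental health); and a
positively skewed salary (mean $55k, sd $10k — modelled lognormal).

Costs are accounted in integer cents internally so that ledger
conservation checks are exact rather than float-tolerant.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum

from .config import INJURY_TYPES, PolicyLevers

__all__ = [
    "WorkerStage",
    "Ledger",
    "InjuredWorker",
    "sample_salary",
    "sample_worker",
    "spawn_cohort",
]


class WorkerStage(str, Enum):
    """A worker's position in the scheme's state chart."""

    GENERAL_POPULATION = "general_population"
    GP = "gp"
    EMERGENCY = "emergency"
    WORKPLACE_CHECK = "workplace_check"
    CLAIM_LODGEMENT = "claim_lodgement"
    CLAIM_ACCEPTED_WAITING = "claim_accepted_waiting"
    TREATMENT = "treatment"
    DISPUTE = "dispute"
    RTW_POOL = "rtw_pool"
    EXITED = "exited"


COST_CATEGORIES = ("gp", "emergency", "treatment", "wage", "occ_rehab",
                   "advertising")


class Ledger:
    """Per-category cost totals held exactly, in integer cents."""

    __slots__ = ("cents",)

    def __init__(self) -> None:
        self.cents: dict[str, int] = {}

    def charge(self, category: str, amount: float) -> int:
        """Add ``amount`` currency units (rounded to cents); returns cents."""
        c = round(amount * 100)
        if c < 0:
            raise ValueError(f"negative charge {amount} to {category}")
        self.cents[category] = self.cents.get(category, 0) + c
        return c

    def charge_cents(self, category: str, cents: int) -> None:
        if cents < 0:
            raise ValueError(f"negative charge {cents} cents to {category}")
        self.cents[category] = self.cents.get(category, 0) + cents

    def get(self, category: str) -> float:
        return self.cents.get(category, 0) / 100.0

    def get_cents(self, category: str) -> int:
        return self.cents.get(category, 0)

    def total(self) -> float:
        return sum(self.cents.values()) / 100.0

    def total_cents(self) -> int:
        return sum(self.cents.values())

    def as_dict(self) -> dict[str, float]:
        return {k: v / 100.0 for k, v in self.cents.items()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, Ledger):
            return NotImplemented
        return {k: v for k, v in self.cents.items() if v} == {
            k: v for k, v in other.cents.items() if v
        }

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Ledger({self.as_dict()})"


def _clamp(x: float, lo: float = 0.0, hi: float = 100.0) -> float:
    return lo if x < lo else hi if x > hi else x


@dataclass
class InjuredWorker:
    """One injured worker flowing through the compensation scheme."""

    id: int
    health: float
    satisfaction: float
    trust: float
    fight_appetite: float
    responsiveness: float
    salary: float
    expectation_wait: int
    injury_type: str
    stage: WorkerStage = WorkerStage.GENERAL_POPULATION
    accepted: str = "pending"            # pending | accepted | rejected
    memory_span: int = 300
    memory: deque = field(default_factory=deque)
    spawn_t: int = 0
    claim_active_since: int | None = None
    lodged_t: int | None = None          # entered the lodgement queue
    dispute_kind: str | None = None      # claim | treatment
    dispute_entered_t: int | None = None
    dispute_count: int = 0
    rtw_mode: str | None = None          # full | partial
    failed_rtw_count: int = 0
    occ_rehab_received: bool = False
    wage_step_cents: int | None = None   # cached full-incapacity per-step wage
    exit_t: int | None = None
    exit_reason: str | None = None
    ledger: Ledger = field(default_factory=Ledger)
    system_charged: Ledger = field(default_factory=Ledger)

    def __post_init__(self) -> None:
        if not (0.0 <= self.health <= 100.0):
            raise ValueError(f"health={self.health} outside [0, 100]")
        for name in ("satisfaction", "trust", "fight_appetite"):
            val = getattr(self, name)
            if not (0.0 <= val <= 100.0):
                raise ValueError(f"{name}={val} outside [0, 100]")
        if not (-1.0 <= self.responsiveness <= 1.0):
            raise ValueError(f"responsiveness={self.responsiveness} outside [-1, 1]")
        if self.salary <= 0:
            raise ValueError(f"salary={self.salary} must be > 0")
        if self.memory.maxlen != self.memory_span:
            self.memory = deque(self.memory, maxlen=self.memory_span)

    # -- psychology scales are always clamped to [0, 100] ---------------
    def bump_trust(self, delta: float) -> None:
        self.trust = _clamp(self.trust + delta)

    def bump_satisfaction(self, delta: float) -> None:
        self.satisfaction = _clamp(self.satisfaction + delta)

    def remember(self, t: int, tag: str) -> None:
        self.memory.append((t, tag))

    def claim_duration(self, t: int) -> int | None:
        """Duration of the accepted claim at time ``t`` (or at exit)."""
        if self.claim_active_since is None:
            return None
        end = self.exit_t if self.exit_t is not None else t
        return end - self.claim_active_since

    @property
    def alive(self) -> bool:
        return self.stage is not WorkerStage.EXITED


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given population mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_salary(rng, mean: float = 55000.0, sd: float = 10000.0) -> float:
    """Draw a salary from a lognormal with the given mean and sd.

    The lognormal is the simplest positively-skewed two-parameter
    family; it is re-parameterised so the *population* mean and sd are
    exactly the configured values.
    """
    mu, sigma = _lognormal_params(mean, sd)
    return math.exp(rng.normal(mu, sigma))


def _truncated_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    # rejection sampling; acceptance rate is high for the defaults used
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return min(max(mean, lo), hi)


def sample_worker(rng, levers: PolicyLevers, t: int, worker_id: int) -> InjuredWorker:
    """Synthesize one newly injured worker at time-step ``t``.

    Entry health is uniform on [entry_health_min, claim_threshold) so
    that entrants are plausibly claim-eligible; trust and satisfaction
    start in the upper half of their scales; fight appetite spans the
    full scale.  The worker is triaged to a GP with probability
    ``p_gp_first``, otherwise to an emergency ward.
    """
    u = rng.random()
    mix = levers.injury_mix
    acc = 0.0
    injury = INJURY_TYPES[-1]
    for itype in INJURY_TYPES:
        acc += mix[itype]
        if u < acc:
            injury = itype
            break
    health = rng.uniform(levers.entry_health_min, levers.claim_threshold)
    trust = rng.uniform(*levers.entry_trust_range)
    satisfaction = rng.uniform(*levers.entry_satisfaction_range)
    fight = rng.uniform(*levers.entry_fight_range)
    responsiveness = _truncated_normal(
        rng, levers.responsiveness_mean, levers.responsiveness_sd, -1.0, 1.0
    )
    salary = sample_salary(rng, levers.salary_mean, levers.salary_sd)
    expectation = max(
        1, round(rng.normal(levers.expectation_wait_mean, levers.expectation_wait_sd))
    )
    stage = WorkerStage.GP if rng.random() < levers.p_gp_first else WorkerStage.EMERGENCY
    return InjuredWorker(
        id=worker_id,
        health=health,
        satisfaction=satisfaction,
        trust=trust,
        fight_appetite=fight,
        responsiveness=responsiveness,
        salary=salary,
        expectation_wait=int(expectation),
        injury_type=injury,
        stage=stage,
        memory_span=min(levers.memory_span, 300),
        spawn_t=t,
    )


def spawn_cohort(state, rng) -> list[InjuredWorker]:
    """Spawn this step's cohort of newly injured workers.

    Workers arrive at ``current_arrival_rate`` per step.  When arrival
    variation is enabled the rate takes a +/-1 random-walk step every 50
    time-steps (never below zero).  A configured mass incident injects
    a one-off extra cohort at its trigger step.
    """
    levers = state.levers
    if (
        levers.arrival_variation_enabled
        and state.t > 0
        and state.t % 50 == 0
    ):
        delta = 1 if rng.random() < 0.5 else -1
        state.current_arrival_rate = max(0, state.current_arrival_rate + delta)
    n = state.current_arrival_rate
    if levers.mass_incident_step is not None and state.t == levers.mass_incident_step:
        n += levers.mass_incident_size
    cohort = []
    for _ in range(n):
        w = sample_worker(rng, levers, state.t, state.next_worker_id)
        state.next_worker_id += 1
        cohort.append(w)
    return cohort
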