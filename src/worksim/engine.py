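"""The master per-time-step scheduler for the compensation scheme.

Each call to :func:`advance` executes one time-step in a fixed phase
order, following the scheme's state chart left to right:

1. spawn the arriving cohort,
2. GP / emergency-department assessments,
3. workplace re-checks (with the small waitlist health drift),
4. claim adjudication up to administrative capacity (FIFO),
5. dispute resolutions,
6. treatment: admissions, denials, health updates, cost accrual,
7. return-to-work attempts (full, employer/partial, failed),
8. termination checks against the maximum claim duration,
9. psychology updates (waits exceeding expectations, contagion),
10. metrics snapshot.

The intra-step ordering is part of the model definition: the source
narrative fixes the topology of the state chart but not the order in
which simultaneous transitions fire.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import PolicyLevers, SimulationConfig, accept_rate_for, validate_levers
from .disputes import decides_to_dispute, event_for, apply_psych_event, resolve_dispute
from .metrics import StepMetrics, snapshot
from .population import InjuredWorker, Ledger, WorkerStage, spawn_cohort
from .treatment import (
    Employer,
    RtwOutcome,
    attempt_employer_rtw,
    accrue_wage_cost,
    check_termination,
    denied_health_update,
    maybe_deny_treatment,
    readiness_with_advertising,
    rtw_gate,
    treat_step,
)

__all__ = [
    "SystemState",
    "advance",
    "assess_at_gp",
    "assess_at_emergency",
    "workplace_recheck",
    "process_lodgement_queue",
    "adjudicate_claim",
    "run_simulation",
    "InvariantError",
]


class InvariantError(RuntimeError):
    """A structural invariant of the system state was breached."""


@dataclass
class SystemState:
    """All mutable simulation state: clock, workers, queues and ledgers."""

    levers: PolicyLevers
    rng: object
    t: int = 0
    workers: dict[int, InjuredWorker] = field(default_factory=dict)
    lodgement_queue: deque = field(default_factory=deque)
    accepted_queue: deque = field(default_factory=deque)
    priority_readmit: deque = field(default_factory=deque)
    treatment_order: list[int] = field(default_factory=list)
    workplace: list[int] = field(default_factory=list)
    disputing: list[int] = field(default_factory=list)
    rtw_pool: list[int] = field(default_factory=list)
    exited: list[InjuredWorker] = field(default_factory=list)
    ledgers: Ledger = field(default_factory=Ledger)
    current_arrival_rate: int = 0
    next_worker_id: int = 0
    counters: dict[str, int] = field(default_factory=lambda: {
        "full_rtw": 0, "partial_rtw": 0, "failed_rtw": 0,
        "disputes": 0, "terminated": 0, "exited": 0,
    })
    exit_duration_sum: float = 0.0
    exit_duration_n: int = 0
    exit_duration_sum_nonterminated: float = 0.0
    exit_duration_n_nonterminated: int = 0
    pending_triage: list[int] = field(default_factory=list)
    total_spawned: int = 0
    record_events: bool = False
    event_log: list[tuple] = field(default_factory=list)

    def inject_worker(self, worker: InjuredWorker) -> None:
        """Add a pre-built worker (test scaffolding), routed by its stage."""
        if worker.id in self.workers:
            raise InvariantError(f"duplicate worker id {worker.id}")
        self.workers[worker.id] = worker
        self.total_spawned += 1
        self.next_worker_id = max(self.next_worker_id, worker.id + 1)
        if worker.stage in (WorkerStage.GP, WorkerStage.EMERGENCY):
            self.pending_triage.append(worker.id)
        elif worker.stage is WorkerStage.WORKPLACE_CHECK:
            self.workplace.append(worker.id)
        elif worker.stage is WorkerStage.CLAIM_LODGEMENT:
            worker.lodged_t = self.t
            self.lodgement_queue.append(worker.id)
        elif worker.stage is WorkerStage.CLAIM_ACCEPTED_WAITING:
            self.accepted_queue.append(worker.id)
        elif worker.stage is WorkerStage.TREATMENT:
            self.treatment_order.append(worker.id)
        elif worker.stage is WorkerStage.DISPUTE:
            if worker.dispute_entered_t is None:
                worker.dispute_entered_t = self.t
            self.disputing.append(worker.id)
        elif worker.stage is WorkerStage.RTW_POOL:
            self.rtw_pool.append(worker.id)

    @classmethod
    def initial(cls, levers: PolicyLevers, rng, record_events: bool = False
                ) -> "SystemState":
        return cls(
            levers=levers,
            rng=rng,
            current_arrival_rate=levers.arrival_rate,
            record_events=record_events,
        )

    @property
    def treatment_occupancy(self) -> int:
        return len(self.treatment_order)

    # -- transitions ----------------------------------------------------
    def log_event(self, worker: InjuredWorker, from_stage: WorkerStage,
                  to_stage: WorkerStage, tag: str) -> None:
        if self.record_events:
            self.event_log.append(
                (self.t, worker.id, from_stage.value, to_stage.value, tag)
            )

    def move(self, worker: InjuredWorker, to_stage: WorkerStage, tag: str) -> None:
        self.log_event(worker, worker.stage, to_stage, tag)
        worker.stage = to_stage

    def exit_worker(self, worker: InjuredWorker, reason: str) -> None:
        self.move(worker, WorkerStage.EXITED, reason)
        worker.exit_t = self.t
        worker.exit_reason = reason
        del self.workers[worker.id]
        self.exited.append(worker)
        self.counters["exited"] += 1
        dur = worker.claim_duration(self.t)
        if dur is not None:
            self.exit_duration_sum += dur
            self.exit_duration_n += 1
            if reason != "terminated":
                self.exit_duration_sum_nonterminated += dur
                self.exit_duration_n_nonterminated += 1

    def enter_lodgement(self, worker: InjuredWorker, tag: str) -> None:
        self.move(worker, WorkerStage.CLAIM_LODGEMENT, tag)
        worker.lodged_t = self.t
        worker.accepted = "pending"
        self.lodgement_queue.append(worker.id)

    def assert_conserved(self) -> None:
        if self.total_spawned != len(self.workers) + len(self.exited):
            raise InvariantError(
                f"worker conservation breached at t={self.t}: spawned "
                f"{self.total_spawned}, live {len(self.workers)}, "
                f"exited {len(self.exited)}"
            )


# ---------------------------------------------------------------------------
# assessment and adjudication operations
# ---------------------------------------------------------------------------

def assess_at_gp(worker: InjuredWorker, levers: PolicyLevers, rng) -> str:
    """GP assessment: refer to claim lodgement or back to the workplace.

    With probability ``gp_accuracy`` the referral matches the true
    comparison of health against the claim threshold; otherwise the GP
    misdiagnoses and refers the opposite way.  The consultation cost
    (mean ``gp_cost_mean``, truncated normal) is recorded against the
    worker only — it reaches the system ledger only if the claim is
    later accepted.
    """
    if worker.stage is not WorkerStage.GP:
        raise ValueError(f"worker {worker.id} is at {worker.stage}, not GP")
    cost = max(0.0, rng.normal(levers.gp_cost_mean, levers.gp_cost_sd))
    worker.ledger.charge("gp", cost)
    truly_eligible = worker.health < levers.claim_threshold
    correct = rng.random() < levers.gp_accuracy
    eligible_call = truly_eligible if correct else not truly_eligible
    return "to_lodgement" if eligible_call else "to_workplace"


def assess_at_emergency(worker: InjuredWorker, levers: PolicyLevers, rng) -> str:
    """Emergency-ward assessment: fixed cost, accurate threshold test.

    Misdiagnosis is attributed to GPs only; the emergency pathway
    applies the same health-vs-threshold comparison without error.
    """
    if worker.stage is not WorkerStage.EMERGENCY:
        raise ValueError(f"worker {worker.id} is at {worker.stage}, not emergency")
    worker.ledger.charge("emergency", levers.ed_cost)
    if worker.health < levers.claim_threshold:
        return "to_lodgement"
    return "to_workplace"


def workplace_recheck(worker: InjuredWorker, levers: PolicyLevers, rng) -> str:
    """One workplace step: waitlist health drift, then the re-check.

    Health drifts up by max(0, N(drift_mean, drift_sd)) — the small
    waitlist effect.  A worker still at or below the claim threshold
    is referred back to claim lodgement and loses trust; one above it
    has recovered and leaves the scheme.
    """
    drift = max(0.0, rng.normal(levers.waitlist_drift_mean, levers.waitlist_drift_sd))
    worker.health = min(worker.health + drift, 100.0)
    if worker.health <= levers.claim_threshold:
        return "to_lodgement"
    return "exit"


def adjudicate_claim(worker: InjuredWorker, levers: PolicyLevers, rng) -> str:
    """Adjudicate one lodged claim; returns ``accepted`` or ``denied``.

    Acceptance probability depends on injury type (acute 90%, chronic
    60%, mental health 40% at defaults).
    """
    rate = accept_rate_for(levers, worker.injury_type)
    return "accepted" if rng.random() < rate else "denied"


def process_lodgement_queue(state: SystemState, levers: PolicyLevers,
                            capacity: int) -> list[tuple[int, str]]:
    """Adjudicate at most ``capacity`` queued claims, FIFO.

    On acceptance the claim start date is recorded and the worker's
    prior GP/emergency costs are transferred to the system ledger.  On
    denial the worker loses trust and either disputes or gives up and
    leaves the scheme.  Returns (worker_id, outcome) events.

    A claim lodged this very step waits at least until the next one:
    assessment takes time even when capacity is spare.
    """
    events: list[tuple[int, str]] = []
    n = 0
    while state.lodgement_queue and n < capacity:
        head = state.lodgement_queue[0]
        worker = state.workers.get(head)
        if (worker is not None and worker.stage is WorkerStage.CLAIM_LODGEMENT
                and worker.lodged_t == state.t):
            break  # FIFO: everything behind was lodged this step too
        wid = state.lodgement_queue.popleft()
        worker = state.workers.get(wid)
        if worker is None or worker.stage is not WorkerStage.CLAIM_LODGEMENT:
            continue  # stale entry
        n += 1
        outcome = adjudicate_claim(worker, levers, state.rng)
        events.append((wid, outcome))
        if outcome == "accepted":
            worker.accepted = "accepted"
            if worker.claim_active_since is None:
                worker.claim_active_since = state.t
            for cat in ("gp", "emergency"):
                cents = worker.ledger.get_cents(cat) - worker.system_charged.get_cents(cat)
                if cents > 0:
                    worker.system_charged.charge_cents(cat, cents)
                    state.ledgers.charge_cents(cat, cents)
            state.move(worker, WorkerStage.CLAIM_ACCEPTED_WAITING, "claim_accepted")
            state.accepted_queue.append(wid)
        else:
            worker.accepted = "rejected"
            apply_psych_event(worker, event_for(levers, "claim_denied"), state.t)
            if decides_to_dispute(worker, levers, state.rng):
                _enter_dispute(state, worker, "claim")
            else:
                state.exit_worker(worker, "claim_denied")
    return events


def _enter_dispute(state: SystemState, worker: InjuredWorker, kind: str) -> None:
    worker.dispute_kind = kind
    worker.dispute_entered_t = state.t
    worker.dispute_count += 1
    state.counters["disputes"] += 1
    state.move(worker, WorkerStage.DISPUTE, f"dispute_{kind}")
    state.disputing.append(worker.id)


# ---------------------------------------------------------------------------
# the per-step scheduler
# ---------------------------------------------------------------------------

def _capacity_multiplier(state: SystemState) -> float:
    """Intermittent shortage shock: capacity halves 10% of steps."""
    if not state.levers.capacity_variation_enabled:
        return 1.0
    return 0.5 if state.rng.random() < 0.1 else 1.0


def advance(state: SystemState, levers: PolicyLevers | None = None) -> StepMetrics:
    """Execute one time-step; returns the step's metrics snapshot."""
    if levers is None:
        levers = state.levers
    rng = state.rng
    t = state.t
    cap_mult = _capacity_multiplier(state)

    # (1) spawn -----------------------------------------------------------
    for worker in spawn_cohort(state, rng):
        state.workers[worker.id] = worker
        state.total_spawned += 1
        state.log_event(worker, WorkerStage.GENERAL_POPULATION, worker.stage,
                        "injured")
        state.pending_triage.append(worker.id)

    # (2) GP / emergency assessments --------------------------------------
    for wid in state.pending_triage:
        worker = state.workers.get(wid)
        if worker is None:
            continue
        if worker.stage is WorkerStage.GP:
            referral = assess_at_gp(worker, levers, rng)
        elif worker.stage is WorkerStage.EMERGENCY:
            referral = assess_at_emergency(worker, levers, rng)
        else:
            continue
        if referral == "to_lodgement":
            state.enter_lodgement(worker, "referred_to_lodgement")
        else:
            state.move(worker, WorkerStage.WORKPLACE_CHECK, "referred_to_workplace")
            state.workplace.append(worker.id)
    state.pending_triage = []

    # (3) workplace re-checks ---------------------------------------------
    if state.workplace:
        # the re-check always routes onward, so the stage is transient
        for wid in state.workplace:
            worker = state.workers.get(wid)
            if worker is None or worker.stage is not WorkerStage.WORKPLACE_CHECK:
                continue
            nxt = workplace_recheck(worker, levers, rng)
            if nxt == "to_lodgement":
                apply_psych_event(
                    worker, event_for(levers, "sent_back_from_workplace"), t
                )
                state.enter_lodgement(worker, "sent_back_from_workplace")
            else:
                state.exit_worker(worker, "recovered_at_workplace")
        state.workplace = []

    # (4) claim adjudication ----------------------------------------------
    claims_cap = int(levers.claims_processing_capacity * cap_mult)
    process_lodgement_queue(state, levers, claims_cap)

    # (5) dispute resolutions ---------------------------------------------
    if state.disputing:
        still_disputing: list[int] = []
        in_dispute_event = event_for(levers, "in_dispute_step")
        for wid in state.disputing:
            worker = state.workers.get(wid)
            if worker is None or worker.stage is not WorkerStage.DISPUTE:
                continue
            apply_psych_event(worker, in_dispute_event, t)
            if t - worker.dispute_entered_t + 1 < levers.dispute_duration:
                still_disputing.append(wid)
                continue
            outcome = resolve_dispute(worker, levers, rng)
            kind = worker.dispute_kind
            worker.dispute_kind = None
            if outcome == "upheld_for_worker":
                apply_psych_event(worker, event_for(levers, "dispute_won"), t)
                if kind == "claim":
                    state.enter_lodgement(worker, "dispute_won_relodge")
                else:  # treatment dispute: directly back into treatment
                    state.move(worker, WorkerStage.CLAIM_ACCEPTED_WAITING,
                               "dispute_won_readmit")
                    state.priority_readmit.append(wid)
            else:
                apply_psych_event(worker, event_for(levers, "dispute_lost"), t)
                if kind == "claim":
                    state.exit_worker(worker, "dispute_lost")
                else:  # re-entry through the claim-acceptance pathway
                    state.move(worker, WorkerStage.CLAIM_ACCEPTED_WAITING,
                               "dispute_lost_requeue")
                    state.accepted_queue.append(wid)
        state.disputing = still_disputing

    # (6) treatment --------------------------------------------------------
    state.treatment_order = [
        wid for wid in state.treatment_order
        if (w := state.workers.get(wid)) is not None
        and w.stage is WorkerStage.TREATMENT
    ]
    treat_cap = int(levers.treatment_capacity * cap_mult)
    # admissions: dispute-won returns first, then the accepted queue
    for queue in (state.priority_readmit, state.accepted_queue):
        while queue and len(state.treatment_order) < treat_cap:
            wid = queue.popleft()
            worker = state.workers.get(wid)
            if (worker is None
                    or worker.stage is not WorkerStage.CLAIM_ACCEPTED_WAITING):
                continue
            state.move(worker, WorkerStage.TREATMENT, "admitted_to_treatment")
            state.treatment_order.append(wid)
    # service, capacity-limited in admission order
    denied_event = event_for(levers, "treatment_denied")
    for wid in state.treatment_order[:treat_cap]:
        worker = state.workers[wid]
        if maybe_deny_treatment(worker, levers, rng):
            denied_health_update(worker, levers, rng)
            apply_psych_event(worker, denied_event, t)
            if decides_to_dispute(worker, levers, rng):
                _enter_dispute(state, worker, "treatment")
        else:
            treat_step(worker, levers, rng, state.ledgers)
    state.treatment_order = [
        wid for wid in state.treatment_order
        if state.workers[wid].stage is WorkerStage.TREATMENT
    ]

    # wage replacement accrues for every live accepted claim
    wage_scale = levers.wage_replacement_fraction / levers.steps_per_year * 100.0
    system_ledger = state.ledgers
    for worker in state.workers.values():
        if worker.accepted != "accepted" or worker.rtw_mode == "full":
            continue
        if worker.rtw_mode == "partial":
            credit = min(worker.health / 100.0, 1.0)
            cents = round((1.0 - credit) * wage_scale * worker.salary)
        else:
            cents = worker.wage_step_cents
            if cents is None:
                cents = worker.wage_step_cents = round(wage_scale * worker.salary)
        worker.ledger.charge_cents("wage", cents)
        worker.system_charged.charge_cents("wage", cents)
        system_ledger.charge_cents("wage", cents)

    # (7) return-to-work ---------------------------------------------------
    if state.rtw_pool:
        partial: list[InjuredWorker] = []
        for wid in state.rtw_pool:
            worker = state.workers.get(wid)
            if worker is None:
                continue
            if worker.rtw_mode == "full":
                state.exit_worker(worker, "full_rtw")
            else:
                partial.append(worker)
        if partial:
            # partial RTW: health keeps improving at the waitlist rate
            drifts = rng.normal(levers.waitlist_drift_mean,
                                levers.waitlist_drift_sd, size=len(partial))
            threshold = levers.claim_threshold
            for worker, drift in zip(partial, drifts):
                if drift > 0.0:
                    worker.health = min(worker.health + drift, 100.0)
                if worker.health >= threshold:
                    worker.rtw_mode = "full"
                    state.counters["full_rtw"] += 1
                    state.log_event(worker, worker.stage, worker.stage,
                                    "partial_to_full_rtw")
        state.rtw_pool = [w.id for w in partial]

    occ_rehab_slots = levers.occ_rehab_capacity if levers.occ_rehab_enabled else 0
    newly_pooled: list[int] = []
    for wid in state.treatment_order:
        worker = state.workers[wid]
        action = rtw_gate(worker, levers)
        if action == "to_rtw_pool":
            worker.rtw_mode = "full"
            state.counters["full_rtw"] += 1
            state.move(worker, WorkerStage.RTW_POOL, "full_rtw_pool")
            newly_pooled.append(wid)
        elif action == "to_employer_attempt":
            base = rng.uniform(0.0, levers.employer_readiness_max)
            employer = Employer(readiness_with_advertising(base, levers))
            outcome, used = attempt_employer_rtw(
                worker, employer, levers, occ_rehab_slots, state.ledgers
            )
            occ_rehab_slots -= used
            if outcome is RtwOutcome.PARTIAL_RTW:
                worker.rtw_mode = "partial"
                state.counters["partial_rtw"] += 1
                state.move(worker, WorkerStage.RTW_POOL, "partial_rtw")
                newly_pooled.append(wid)
            else:
                state.counters["failed_rtw"] += 1
                state.log_event(worker, worker.stage, worker.stage, "failed_rtw")
    if newly_pooled:
        pooled = set(newly_pooled)
        state.treatment_order = [
            wid for wid in state.treatment_order if wid not in pooled
        ]
        state.rtw_pool.extend(newly_pooled)

    # (8) termination ------------------------------------------------------
    if math.isfinite(levers.max_claim_duration):
        for worker in list(state.workers.values()):
            if worker.accepted == "accepted" and check_termination(worker, levers, t):
                state.counters["terminated"] += 1
                state.exit_worker(worker, "terminated")

    # (9) psychology -------------------------------------------------------
    wait_event = event_for(levers, "wait_exceeded_expectation")
    for wid in state.lodgement_queue:
        worker = state.workers.get(wid)
        if worker is None or worker.stage is not WorkerStage.CLAIM_LODGEMENT:
            continue
        if t - worker.lodged_t > worker.expectation_wait:
            apply_psych_event(worker, wait_event, t)
    if levers.mistrust_contagion_enabled:
        _spread_mistrust(state, levers)
    if levers.advertising_spend > 0:
        state.ledgers.charge("advertising", levers.advertising_spend)

    # (10) metrics ---------------------------------------------------------
    state.assert_conserved()
    state.t = t + 1
    return snapshot(state)


def _spread_mistrust(state: SystemState, levers: PolicyLevers) -> None:
    """Minimal story-sharing contagion: workers in lodgement or dispute
    occasionally copy a lower trust value from a same-stage peer."""
    for stage_ids in (list(state.lodgement_queue), state.disputing):
        peers = [
            state.workers[wid] for wid in stage_ids if wid in state.workers
        ]
        if len(peers) < 2:
            continue
        for worker in peers:
            if state.rng.random() < levers.mistrust_contagion_rate:
                other = peers[int(state.rng.random() * len(peers))]
                if other.trust < worker.trust:
                    worker.trust = other.trust


def run_simulation(
    config: SimulationConfig,
    rng=None,
    record_events: bool = False,
) -> tuple[list[StepMetrics], SystemState]:
    """Run a full simulation; returns the metrics series and final state."""
    violations = validate_levers(config.levers)
    if violations:
        raise ValueError("invalid levers: " + "; ".join(violations))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = SystemState.initial(config.levers, rng, record_events=record_events)
    series = [advance(state) for _ in range(config.n_steps)]
    return series, state
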