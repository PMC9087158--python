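"""Health dynamics under treatment, cost accrual and return-to-work.

Treatment closes 5% of the gap between current health and the
100-point maximum per step, scaled by the worker's individual
responsiveness multiplier, plus bounded symmetric noise — so recovery
is fast early in a claim and slows near full health.  Each delivered
service costs ~$100 (sd $20); workers on accepted claims accrue wage
replacement at 80% of salary, reduced pro-rata during partial
return-to-work.

Return-to-work has three pathways: *full* RTW once health reaches the
claim threshold; *partial* RTW via the employer before full recovery
(requires the employer to be ready to cover the health shortfall,
optionally bridged by $10,000 occupational rehabilitation support);
and *failed* RTW when the employer is not ready, returning the worker
to treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .config import PolicyLevers
from .population import InjuredWorker, Ledger

__all__ = [
    "Employer",
    "RtwOutcome",
    "treat_step",
    "maybe_deny_treatment",
    "accrue_wage_cost",
    "rtw_gate",
    "attempt_employer_rtw",
    "apply_occ_rehab",
    "readiness_with_advertising",
    "check_termination",
]


class RtwOutcome(str, Enum):
    FULL_RTW = "full_rtw"
    PARTIAL_RTW = "partial_rtw"
    FAILED_RTW = "failed_rtw"


@dataclass
class Employer:
    """Per-attempt employer context for a returning worker."""

    readiness: float  # points in [0, 100]

    def __post_init__(self) -> None:
        self.readiness = min(max(self.readiness, 0.0), 100.0)


def readiness_with_advertising(base_readiness: float, levers: PolicyLevers) -> float:
    """Employer readiness after the advertising effect.

    Advertising spend s raises readiness by a saturating gain
    g(s) = g_max * s / (s + s_half); the result is clamped to [0, 100].
    Zero spend leaves readiness unchanged.
    """
    s = levers.advertising_spend
    gain = levers.advertising_readiness_gain * s / (s + levers.advertising_half_saturation)
    return min(max(base_readiness + gain, 0.0), 100.0)


def treat_step(
    worker: InjuredWorker,
    levers: PolicyLevers,
    rng,
    system_ledger: Ledger | None = None,
) -> InjuredWorker:
    """Apply one time-step of delivered treatment.

    health <- clamp(health + r * rho * (100 - health) + eps, 0, 100)
    with recovery rate r (default 0.05), responsiveness rho, and eps
    uniform on +/- the noise amplitude.  The service cost (mean $100,
    sd $20, truncated at zero) is recorded against the worker and the
    system.
    """
    gap = 100.0 - worker.health
    gain = levers.recovery_rate * gap * worker.responsiveness
    eps = 0.0
    if levers.treatment_noise_amplitude > 0:
        amp = levers.treatment_noise_amplitude
        eps = rng.uniform(-amp, amp)
    worker.health = min(max(worker.health + gain + eps, 0.0), 100.0)
    cost = max(0.0, rng.normal(levers.treatment_cost_mean, levers.treatment_cost_sd))
    cents = worker.ledger.charge("treatment", cost)
    worker.system_charged.charge_cents("treatment", cents)
    if system_ledger is not None:
        system_ledger.charge_cents("treatment", cents)
    return worker


def maybe_deny_treatment(worker: InjuredWorker, levers: PolicyLevers, rng) -> bool:
    """Decide whether this step's treatment is denied.

    On denial the caller applies noise-only health change, skips the
    service cost, decrements trust and triggers the dispute decision.
    """
    return rng.random() < levers.treatment_denial_rate


def denied_health_update(worker: InjuredWorker, levers: PolicyLevers, rng) -> None:
    """Health change for a denied step: random noise only, no recovery."""
    if levers.treatment_noise_amplitude > 0:
        amp = levers.treatment_noise_amplitude
        worker.health = min(max(worker.health + rng.uniform(-amp, amp), 0.0), 100.0)


def accrue_wage_cost(
    worker: InjuredWorker,
    levers: PolicyLevers,
    fitness_credit: float,
    system_ledger: Ledger | None = None,
) -> float:
    """Accrue one step of wage replacement; returns the amount charged.

    cost = (1 - fitness_credit) * wage_replacement_fraction
           * salary / steps_per_year

    fitness_credit is 0 while fully off work and health/100 during
    partial return-to-work (a 75%-fit worker costs 25% x 0.8 of
    salary).  Charged to the worker's and the system's ledgers.
    """
    if not (0.0 <= fitness_credit <= 1.0):
        raise ValueError(f"fitness_credit={fitness_credit} outside [0, 1]")
    per_step_salary = worker.salary / levers.steps_per_year
    amount = (1.0 - fitness_credit) * levers.wage_replacement_fraction * per_step_salary
    cents = worker.ledger.charge("wage", amount)
    worker.system_charged.charge_cents("wage", cents)
    if system_ledger is not None:
        system_ledger.charge_cents("wage", cents)
    return cents / 100.0


def rtw_gate(worker: InjuredWorker, levers: PolicyLevers) -> str:
    """Route a treated worker toward return-to-work.

    Full RTW opens at the claim threshold.  Under the ``encourage``
    policy, workers at or above the early-RTW health floor are sent to
    attempt a return through their employer before full recovery;
    under ``neutral`` and ``discourage`` no employer routing occurs.
    Returns one of ``to_rtw_pool``, ``to_employer_attempt``,
    ``stay_in_treatment``.
    """
    if worker.health >= levers.claim_threshold:
        return "to_rtw_pool"
    if (
        levers.rtw_policy == "encourage"
        and worker.health >= levers.early_rtw_health_floor
    ):
        return "to_employer_attempt"
    return "stay_in_treatment"


def apply_occ_rehab(
    worker: InjuredWorker,
    employer: Employer,
    levers: PolicyLevers,
    system_ledger: Ledger | None = None,
) -> None:
    """Bridge the readiness shortfall with occupational rehabilitation.

    Readiness is topped up to cover the worker's health shortfall and
    the scheme is charged the occ-rehab fee once per supported worker.
    """
    shortfall = levers.claim_threshold - worker.health
    if employer.readiness < shortfall:
        employer.readiness = min(shortfall, 100.0)
    if not worker.occ_rehab_received:
        cents = worker.ledger.charge("occ_rehab", levers.occ_rehab_cost)
        worker.system_charged.charge_cents("occ_rehab", cents)
        if system_ledger is not None:
            system_ledger.charge_cents("occ_rehab", cents)
        worker.occ_rehab_received = True


def attempt_employer_rtw(
    worker: InjuredWorker,
    employer: Employer,
    levers: PolicyLevers,
    occ_rehab_slots: int = 0,
    system_ledger: Ledger | None = None,
) -> tuple[RtwOutcome, int]:
    """One attempt at an early return through the employer.

    The employer accepts if readiness covers the health shortfall to
    the claim threshold (a partial RTW).  Otherwise, if occupational
    rehabilitation is enabled and a per-step slot remains, support
    bridges the gap; failing that the attempt is a failed RTW and the
    worker goes back to treatment.  Returns the outcome and the number
    of occ-rehab slots consumed (0 or 1).
    """
    shortfall = levers.claim_threshold - worker.health
    if employer.readiness >= shortfall:
        return RtwOutcome.PARTIAL_RTW, 0
    if levers.occ_rehab_enabled and occ_rehab_slots > 0:
        apply_occ_rehab(worker, employer, levers, system_ledger)
        return RtwOutcome.PARTIAL_RTW, 1
    worker.failed_rtw_count += 1
    return RtwOutcome.FAILED_RTW, 0


def check_termination(worker: InjuredWorker, levers: PolicyLevers, t: int) -> bool:
    """True when the claim's duration has surpassed the maximum limit.

    "Surpassed" is read strictly: a duration exactly equal to the
    limit does not terminate.
    """
    if worker.claim_active_since is None:
        return False
    return (t - worker.claim_active_since) > levers.max_claim_duration
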