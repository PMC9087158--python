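"""Trust/satisfaction dynamics and the dispute loop.

Workers who receive unfavourable decisions — a denied claim, denied
treatment, being sent back from the workplace, or waits exceeding
their expectations — lose trust (and sometimes satisfaction) in the
scheme.  Low trust combined with a high appetite for fighting
decisions makes a worker likely to dispute the next unfavourable
decision; workers in dispute keep losing trust and satisfaction for as
long as the dispute runs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PolicyLevers
from .population import InjuredWorker

__all__ = [
    "PsychEvent",
    "dispute_probability",
    "decides_to_dispute",
    "resolve_dispute",
    "apply_psych_event",
]


@dataclass(frozen=True)
class PsychEvent:
    """A psychologically salient event with trust/satisfaction deltas."""

    tag: str
    trust_delta: float
    satisfaction_delta: float


def event_for(levers: PolicyLevers, tag: str) -> PsychEvent:
    """Look up the configured deltas for an event tag."""
    trust_d, sat_d = levers.psych_deltas[tag]
    return PsychEvent(tag, trust_d, sat_d)


def apply_psych_event(worker: InjuredWorker, event: PsychEvent, t: int) -> InjuredWorker:
    """Apply an event's deltas (clamped to [0, 100]) and record it in memory."""
    worker.bump_trust(event.trust_delta)
    worker.bump_satisfaction(event.satisfaction_delta)
    worker.remember(t, event.tag)
    return worker


def dispute_probability(worker: InjuredWorker) -> float:
    """Probability that a worker disputes an unfavourable decision.

    p = (fight_appetite / 100) * (1 - trust / 100): strictly increasing
    in the appetite for fighting decisions and strictly decreasing in
    trust — the two stated behavioural drivers.  A fully trusting
    worker never disputes; a zero-trust, maximum-fight worker always
    does.
    """
    return (worker.fight_appetite / 100.0) * (1.0 - worker.trust / 100.0)


def decides_to_dispute(worker: InjuredWorker, levers: PolicyLevers, rng) -> bool:
    """Bernoulli dispute decision, honouring the optional per-worker cap."""
    cap = levers.max_disputes_per_worker
    if cap is not None and worker.dispute_count >= cap:
        return False
    return rng.random() < dispute_probability(worker)


def resolve_dispute(worker: InjuredWorker, levers: PolicyLevers, rng) -> str:
    """Resolve a worker's dispute; returns ``upheld_for_worker`` or
    ``upheld_against_worker``.

    The caller routes the worker afterwards: a successful claim dispute
    re-enters the lodgement queue; a failed one exits the scheme.  A
    successful treatment dispute returns the worker directly to
    treatment; a failed one re-enters via the claim-acceptance pathway.
    """
    if rng.random() < levers.dispute_success_rate:
        return "upheld_for_worker"
    return "upheld_against_worker"
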