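"""Empirical parameter-echo measurements.

Each function re-measures one of the scheme's configured parameters as
an *emergent* quantity of the simulator — e.g. the claim-acceptance
percentage observed over many adjudications, or the mean cost actually
recorded per GP visit — rather than reading the lever back.  They are
used by the acceptance harness and are handy for sanity-checking a
reconfigured model.
"""

from __future__ import annotations

import numpy as np

from .config import PolicyLevers
from .engine import adjudicate_claim, assess_at_gp
from .fixtures import make_worker
from .population import WorkerStage, sample_worker
from .treatment import accrue_wage_cost, treat_step

__all__ = [
    "measure_triage_split",
    "measure_gp_visit_cost",
    "measure_acceptance_rate",
    "measure_recovery_gain_pct",
    "measure_treatment_cost",
    "measure_partial_wage_pct",
]


def measure_triage_split(n: int, seed: int, levers: PolicyLevers | None = None) -> float:
    """Percentage of newly injured workers first presenting to a GP."""
    levers = levers or PolicyLevers()
    rng = np.random.default_rng(seed)
    gp = sum(
        sample_worker(rng, levers, 0, i).stage is WorkerStage.GP
        for i in range(n)
    )
    return 100.0 * gp / n


def measure_gp_visit_cost(n: int, seed: int, levers: PolicyLevers | None = None) -> float:
    """Mean cost recorded against the worker per GP visit, in $."""
    levers = levers or PolicyLevers()
    rng = np.random.default_rng(seed)
    total_cents = 0
    for i in range(n):
        w = make_worker({"id": i, "health": 40.0, "stage": WorkerStage.GP})
        assess_at_gp(w, levers, rng)
        total_cents += w.ledger.get_cents("gp")
    return total_cents / n / 100.0


def measure_acceptance_rate(
    injury_type: str, n: int, seed: int, levers: PolicyLevers | None = None
) -> float:
    """Empirical claim-acceptance percentage for one injury type."""
    levers = levers or PolicyLevers()
    rng = np.random.default_rng(seed)
    w = make_worker({"stage": WorkerStage.CLAIM_LODGEMENT,
                     "injury_type": injury_type})
    accepted = sum(
        adjudicate_claim(w, levers, rng) == "accepted" for _ in range(n)
    )
    return 100.0 * accepted / n


def measure_recovery_gain_pct(seed: int = 0) -> float:
    """One-step treated health gain as a percentage of the health gap.

    Measured on a worker with health 0 and responsiveness 1.0 with the
    noise term disabled, so the gain is the pure recovery rate.
    """
    levers = PolicyLevers(treatment_noise_amplitude=0.0)
    rng = np.random.default_rng(seed)
    w = make_worker({"health": 0.0, "responsiveness": 1.0,
                     "stage": WorkerStage.TREATMENT})
    treat_step(w, levers, rng)
    return 100.0 * (w.health - 0.0) / 100.0


def measure_treatment_cost(n: int, seed: int, levers: PolicyLevers | None = None) -> float:
    """Mean cost recorded per delivered treatment service, in $."""
    levers = levers or PolicyLevers()
    rng = np.random.default_rng(seed)
    w = make_worker({"health": 50.0, "stage": WorkerStage.TREATMENT})
    before = w.ledger.get_cents("treatment")
    for _ in range(n):
        w.health = 50.0
        treat_step(w, levers, rng)
    return (w.ledger.get_cents("treatment") - before) / n / 100.0


def measure_partial_wage_pct(fitness_credit: float = 0.75) -> float:
    """Wage paid during partial RTW as a % of the full entitlement."""
    levers = PolicyLevers()
    base = accrue_wage_cost(make_worker({}), levers, 0.0)
    partial = accrue_wage_cost(make_worker({}), levers, fitness_credit)
    return 100.0 * partial / base
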