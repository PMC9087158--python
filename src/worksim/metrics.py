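"""Per-step monitors and run summaries.

Mirrors the scheme's eight headline performance variables: workers in
system, mean satisfaction, mean trust (also split by claim acceptance
status), mean medical treatment costs, total system costs, wage
replacement costs, mean claim duration at exit, and mean worker
health.  Means over empty groups are reported as missing (None),
never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import pandas as pd

from .population import WorkerStage

__all__ = [
    "StepMetrics",
    "OUTCOME_VARIABLES",
    "snapshot",
    "trust_by_acceptance",
    "mean_claim_duration_at_exit",
    "write_timeseries",
    "read_timeseries",
    "metrics_frame",
]

#: The eight end-of-run performance variables compared across policy
#: conditions.
OUTCOME_VARIABLES = (
    "n_in_system",
    "mean_satisfaction",
    "mean_trust",
    "cum_treatment_cost",
    "cum_total_cost",
    "cum_wage_cost",
    "mean_claim_duration_at_exit",
    "mean_health",
)

_STAGE_COUNT_FIELDS = {
    WorkerStage.GP: "n_gp",
    WorkerStage.EMERGENCY: "n_emergency",
    WorkerStage.WORKPLACE_CHECK: "n_workplace_check",
    WorkerStage.CLAIM_LODGEMENT: "n_claim_lodgement",
    WorkerStage.CLAIM_ACCEPTED_WAITING: "n_claim_accepted_waiting",
    WorkerStage.TREATMENT: "n_treatment",
    WorkerStage.DISPUTE: "n_dispute",
    WorkerStage.RTW_POOL: "n_rtw_pool",
}


@dataclass
class StepMetrics:
    """Aggregate monitors for one time-step."""

    t: int
    n_in_system: int = 0
    n_gp: int = 0
    n_emergency: int = 0
    n_workplace_check: int = 0
    n_claim_lodgement: int = 0
    n_claim_accepted_waiting: int = 0
    n_treatment: int = 0
    n_dispute: int = 0
    n_rtw_pool: int = 0
    mean_health: float | None = None
    mean_trust: float | None = None
    mean_satisfaction: float | None = None
    mean_trust_accepted: float | None = None
    mean_trust_rejected: float | None = None
    cum_treatment_cost: float = 0.0
    cum_wage_cost: float = 0.0
    cum_occ_rehab_cost: float = 0.0
    cum_advertising_cost: float = 0.0
    cum_gp_cost: float = 0.0
    cum_emergency_cost: float = 0.0
    cum_total_cost: float = 0.0
    n_full_rtw: int = 0
    n_partial_rtw: int = 0
    n_failed_rtw: int = 0
    n_disputes: int = 0
    n_terminated: int = 0
    n_exited: int = 0
    mean_claim_duration_at_exit: float | None = None


def _mean(total: float, n: int) -> float | None:
    return total / n if n else None


def snapshot(state) -> StepMetrics:
    """Pure read of the current system state into a StepMetrics row."""
    m = StepMetrics(t=state.t)
    n = 0
    health_sum = trust_sum = sat_sum = 0.0
    stage_counts: dict[WorkerStage, int] = {}
    for w in state.workers.values():
        n += 1
        health_sum += w.health
        trust_sum += w.trust
        sat_sum += w.satisfaction
        stage_counts[w.stage] = stage_counts.get(w.stage, 0) + 1
    m.n_in_system = n
    for stage, attr in _STAGE_COUNT_FIELDS.items():
        setattr(m, attr, stage_counts.get(stage, 0))
    m.mean_health = _mean(health_sum, n)
    m.mean_trust = _mean(trust_sum, n)
    m.mean_satisfaction = _mean(sat_sum, n)
    m.mean_trust_accepted, m.mean_trust_rejected = trust_by_acceptance(state)

    led = state.ledgers
    m.cum_treatment_cost = led.get("treatment")
    m.cum_wage_cost = led.get("wage")
    m.cum_occ_rehab_cost = led.get("occ_rehab")
    m.cum_advertising_cost = led.get("advertising")
    m.cum_gp_cost = led.get("gp")
    m.cum_emergency_cost = led.get("emergency")
    m.cum_total_cost = led.total_cents() / 100.0

    m.n_full_rtw = state.counters["full_rtw"]
    m.n_partial_rtw = state.counters["partial_rtw"]
    m.n_failed_rtw = state.counters["failed_rtw"]
    m.n_disputes = state.counters["disputes"]
    m.n_terminated = state.counters["terminated"]
    m.n_exited = state.counters["exited"]
    m.mean_claim_duration_at_exit = _mean(
        state.exit_duration_sum, state.exit_duration_n
    )
    return m


def mean_claim_duration_at_exit(state, include_terminated: bool = True
                                ) -> float | None:
    """Mean accepted-claim duration over exited workers.

    Terminated claims are included by default; excluding them
    (``include_terminated=False``) is a sensitivity variant, since
    termination right-censors the longest claims at the duration limit.
    """
    if include_terminated:
        return _mean(state.exit_duration_sum, state.exit_duration_n)
    return _mean(
        state.exit_duration_sum_nonterminated,
        state.exit_duration_n_nonterminated,
    )


def trust_by_acceptance(state) -> tuple[float | None, float | None]:
    """Mean trust over live + exited workers, split by claim acceptance.

    Returns (mean trust | accepted, mean trust | rejected); a group
    with no members yields None.
    """
    acc_sum = rej_sum = 0.0
    acc_n = rej_n = 0
    for group in (state.workers.values(), state.exited):
        for w in group:
            if w.accepted == "accepted":
                acc_sum += w.trust
                acc_n += 1
            elif w.accepted == "rejected":
                rej_sum += w.trust
                rej_n += 1
    return _mean(acc_sum, acc_n), _mean(rej_sum, rej_n)


def metrics_frame(series: list[StepMetrics]) -> pd.DataFrame:
    """Wide DataFrame: one row per step, one column per monitor."""
    cols = [f.name for f in fields(StepMetrics)]
    return pd.DataFrame(
        [{c: getattr(m, c) for c in cols} for m in series], columns=cols
    )


def write_timeseries(series: list[StepMetrics], path) -> None:
    """Write the wide CSV (one row per step) and a tidy variant.

    The tidy file, ``<stem>_tidy.csv`` next to the wide one, has one
    row per (t, metric, value).  Both round-trip losslessly through
    :func:`read_timeseries`.
    """
    if not series:
        raise ValueError("cannot write an empty metrics series")
    from pathlib import Path

    path = Path(path)
    wide = metrics_frame(series)
    wide.to_csv(path, index=False)
    tidy = wide.melt(id_vars=["t"], var_name="metric", value_name="value")
    tidy.to_csv(path.with_name(path.stem + "_tidy.csv"), index=False)


def read_timeseries(path) -> list[StepMetrics]:
    """Read a wide metrics CSV back into StepMetrics objects."""
    df = pd.read_csv(path)
    int_fields = {
        f.name for f in fields(StepMetrics) if f.type in ("int", int)
    }
    out = []
    for row in df.to_dict("records"):
        kwargs = {}
        for k, v in row.items():
            if isinstance(v, float) and math.isnan(v):
                kwargs[k] = None
            elif k in int_fields:
                kwargs[k] = int(v)
            else:
                kwargs[k] = v
        out.append(StepMetrics(**kwargs))
    return out
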