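"""Factorial policy experiments: a parameter-sweep runner.

The default design crosses the return-to-work promotion policy
(discourage / neutral / encourage) with occupational rehabilitation
support (off / on): a six-condition matrix run for 2000 time-steps per
replicate, with the eight performance variables read off at the final
step.  Replicate seeds are paired across conditions so that condition
contrasts share worker-attribute streams (variance reduction).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .config import PolicyLevers, SimulationConfig, validate_levers
from .engine import run_simulation
from .metrics import OUTCOME_VARIABLES, StepMetrics

__all__ = [
    "ExperimentDesign",
    "default_matrix",
    "run_condition",
    "run_matrix",
    "condition_means",
]

_SEED_MOD = 2**31 - 1


@dataclass
class ExperimentDesign:
    """Factors x levels x replicates x horizon."""

    factors: dict[str, list] = field(default_factory=dict)
    n_reps: int = 30
    n_steps: int = 2000
    base_seed: int = 0
    base_levers: PolicyLevers = field(default_factory=PolicyLevers)
    output: str | None = None

    def conditions(self) -> list[dict]:
        """All factor/level combinations, in a stable order."""
        names = list(self.factors)
        combos = product(*(self.factors[n] for n in names))
        return [dict(zip(names, levels)) for levels in combos]

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps={self.n_reps} must be >= 1")
        if self.n_steps < 1:
            raise ValueError(f"n_steps={self.n_steps} must be >= 1")
        if self.factors and not self.conditions():
            raise ValueError("every factor needs at least one level")


def default_matrix(base_seed: int = 0, n_reps: int = 30) -> ExperimentDesign:
    """The shipped six-condition matrix: 3 RTW policies x occ-rehab on/off."""
    return ExperimentDesign(
        factors={
            "rtw_policy": ["discourage", "neutral", "encourage"],
            "occ_rehab_enabled": [False, True],
        },
        n_reps=n_reps,
        n_steps=2000,
        base_seed=base_seed,
    )


def replicate_seed(base_seed: int, rep: int) -> int:
    """Deterministic per-replicate seed, shared by every condition.

    The seed depends on the replicate index only, so replicate i draws
    the same worker-attribute stream in every condition.
    """
    return (base_seed * 1_000_003 + rep * 7_919 + 17) % _SEED_MOD


def run_condition(
    levers: PolicyLevers, n_steps: int, seed: int
) -> tuple[StepMetrics, list[StepMetrics]]:
    """One complete simulation of one condition; deterministic given seed."""
    config = SimulationConfig(n_steps=n_steps, seed=seed, levers=levers)
    series, _ = run_simulation(config)
    return series[-1], series


def run_matrix(design: ExperimentDesign, progress: bool = False) -> pd.DataFrame:
    """Run every (condition, replicate); returns a tidy results table.

    One row per run with the factor levels, the replicate index and
    seed, and the final-step value of each outcome variable.  A failed
    replicate is recorded with an ``error`` tag and the others proceed.
    """
    rows = []
    conditions = design.conditions()
    for cond_idx, cond in enumerate(conditions):
        violations = validate_levers(
            dataclasses.replace(design.base_levers, **cond)
        )
        if violations:
            raise ValueError(
                f"condition {cond} invalid: " + "; ".join(violations)
            )
        for rep in range(design.n_reps):
            seed = replicate_seed(design.base_seed, rep)
            levers = dataclasses.replace(design.base_levers, **cond)
            row: dict = {"condition": cond_idx, **cond, "rep": rep, "seed": seed,
                         "error": None}
            try:
                final, _ = run_condition(levers, design.n_steps, seed)
                for name in OUTCOME_VARIABLES:
                    row[name] = getattr(final, name)
            except Exception as exc:  # partial-failure policy
                row["error"] = f"{type(exc).__name__}: {exc}"
                for name in OUTCOME_VARIABLES:
                    row[name] = np.nan
            rows.append(row)
            if progress:
                print(f"condition {cond_idx + 1}/{len(conditions)} "
                      f"rep {rep + 1}/{design.n_reps} done")
    df = pd.DataFrame(rows)
    if design.output:
        df.to_csv(design.output, index=False)
    return df


def condition_means(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition means and standard errors of the outcome variables."""
    ok = results[results["error"].isna()]
    factor_cols = [
        c for c in results.columns
        if c not in {"condition", "rep", "seed", "error", *OUTCOME_VARIABLES}
    ]
    grouped = ok.groupby(["condition"] + factor_cols, dropna=False)
    means = grouped[list(OUTCOME_VARIABLES)].mean().add_suffix("_mean")
    sems = grouped[list(OUTCOME_VARIABLES)].sem(ddof=1).add_suffix("_se")
    n = grouped.size().rename("n_reps")
    return pd.concat([means, sems, n], axis=1).reset_index()
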