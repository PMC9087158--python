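"""Deterministic test scaffolding: template workers, scripted random
sources, and micro-scenarios that exercise individual transitions.

A :class:`ScriptedRandom` is a drop-in random source whose draws come
from fixed per-method queues, so the engine runs byte-identically
under test and in production.  A :class:`ScenarioScript` bundles a
worker template, lever overrides, forced draws and the expected
transition sequence; :func:`play_script` runs the engine on it and
returns the observed transition trace.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .config import PolicyLevers, config_from_dict
from .engine import SystemState, advance
from .population import InjuredWorker, WorkerStage

__all__ = [
    "make_worker",
    "ScriptedRandom",
    "ScenarioScript",
    "play_script",
    "load_scenario",
]

_WORKER_DEFAULTS = dict(
    id=0,
    health=50.0,
    satisfaction=75.0,
    trust=75.0,
    fight_appetite=50.0,
    responsiveness=0.6,
    salary=55000.0,
    expectation_wait=35,
    injury_type="acute_physical",
)

_WORKER_FIELDS = {f.name for f in dataclasses.fields(InjuredWorker)}


def make_worker(overrides: dict | None = None) -> InjuredWorker:
    """Build a defaulted worker with the given field overrides.

    Unknown field names and invariant breaches raise ``ValueError``.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _WORKER_FIELDS
    if unknown:
        raise ValueError(f"unknown worker fields: {sorted(unknown)}")
    if "stage" in overrides and not isinstance(overrides["stage"], WorkerStage):
        overrides["stage"] = WorkerStage(overrides["stage"])
    kwargs = {**_WORKER_DEFAULTS, **overrides}
    return InjuredWorker(**kwargs)


class ScriptExhausted(RuntimeError):
    """A scripted random source ran out of forced draws."""


class ScriptedRandom:
    """A random source returning pre-scripted values.

    ``script`` maps a method name (``random``, ``uniform``, ``normal``)
    to a FIFO list of values returned verbatim on successive calls
    (arguments such as the uniform bounds are ignored — the scripted
    value *is* the draw).  When a queue is exhausted the source either
    raises :class:`ScriptExhausted` (strict mode, the default) or falls
    back to a deterministic neutral value: 0.5 for ``random``, the
    interval midpoint for ``uniform`` and the mean for ``normal``.
    """

    def __init__(self, script: dict[str, list[float]] | None = None,
                 strict: bool = True) -> None:
        self.script = {k: list(v) for k, v in (script or {}).items()}
        self.strict = strict
        self.calls: list[tuple[str, float]] = []

    def _next(self, method: str, fallback: float) -> float:
        queue = self.script.get(method)
        if queue:
            value = queue.pop(0)
        elif self.strict:
            raise ScriptExhausted(f"no scripted draws left for {method!r}")
        else:
            value = fallback
        self.calls.append((method, value))
        return value

    def random(self) -> float:
        return self._next("random", 0.5)

    def uniform(self, low: float = 0.0, high: float = 1.0) -> float:
        return self._next("uniform", (low + high) / 2.0)

    def normal(self, loc: float = 0.0, scale: float = 1.0, size=None):
        if size is None:
            return self._next("normal", loc)
        import numpy as np

        return np.array([self._next("normal", loc) for _ in range(size)])


@dataclass
class ScenarioScript:
    """A worker template + forced draws + expected transition tags."""

    worker: dict = field(default_factory=dict)
    levers: dict = field(default_factory=dict)
    draws: dict[str, list[float]] = field(default_factory=dict)
    n_steps: int = 1
    strict: bool = False
    expected_transitions: list[str] = field(default_factory=list)

    def build_levers(self) -> PolicyLevers:
        # reuse the config loader's validation of lever names and ranges
        return config_from_dict({"levers": self.levers}).levers


def play_script(script: ScenarioScript) -> list[tuple[int, str, str, str]]:
    """Run the engine on a scripted scenario; returns the transition trace.

    The trace is a list of (t, from_stage, to_stage, event_tag) for the
    scripted worker, suitable for comparison against
    ``script.expected_transitions`` (which lists event tags only).
    """
    levers = script.build_levers()
    rng = ScriptedRandom(script.draws, strict=script.strict)
    state = SystemState.initial(levers, rng, record_events=True)
    worker = make_worker(script.worker)
    state.inject_worker(worker)
    for _ in range(script.n_steps):
        advance(state)
    return [
        (t, frm, to, tag)
        for (t, wid, frm, to, tag) in state.event_log
        if wid == worker.id
    ]


def load_scenario(path: str | Path) -> ScenarioScript:
    """Load a YAML scenario file into a :class:`ScenarioScript`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return ScenarioScript(
        worker=raw.get("worker", {}),
        levers=raw.get("levers", {}),
        draws={k: list(v) for k, v in raw.get("draws", {}).items()},
        n_steps=int(raw.get("n_steps", 1)),
        strict=bool(raw.get("strict", False)),
        expected_transitions=list(raw.get("expected_transitions", [])),
    )
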