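"""Policy levers and simulation settings.

Every observer-adjustable parameter of the scheme lives in
:class:`PolicyLevers`: claim-eligibility thresholds, adjudication
acceptance rates by injury type, administrative and treatment
capacities, cost parameters, the return-to-work policy, occupational
rehabilitation and advertising settings, and the optional shock
toggles.  A :class:`SimulationConfig` wraps the levers together with
the run horizon and seed.

Configs are plain YAML files with a flat ``levers:`` mapping.  Unknown
keys are an error (this catches typos in lever names); omitted keys
take the documented defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "PolicyLevers",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "validate_levers",
    "serialize_config",
    "DEFAULT_PSYCH_DELTAS",
]

INJURY_TYPES = ("acute_physical", "chronic_physical", "mental_health")
RTW_POLICIES = ("discourage", "neutral", "encourage")

# Trust / satisfaction point changes per psychological event.  The
# directions are fixed by the model narrative (adverse events erode
# trust, dispute wins restore a little); the magnitudes are levers.
DEFAULT_PSYCH_DELTAS: dict[str, tuple[float, float]] = {
    "claim_denied": (-5.0, 0.0),
    "treatment_denied": (-5.0, 0.0),
    "sent_back_from_workplace": (-2.0, 0.0),
    "wait_exceeded_expectation": (-1.0, 0.0),
    "in_dispute_step": (-1.0, -1.0),
    "dispute_lost": (-5.0, -5.0),
    "dispute_won": (2.0, 0.0),
}


class ConfigError(ValueError):
    """Raised for unreadable, malformed or invalid configuration."""


@dataclass
class PolicyLevers:
    """All observer-manipulable settings of the scheme.

    Units: health / trust / satisfaction / fight are points on 0-100
    scales; costs are currency units; capacities are workers per
    time-step; durations are time-steps.
    """

    # -- claim eligibility and triage ------------------------------------
    claim_threshold: float = 95.0          # health below this is claim-eligible
    p_gp_first: float = 0.5                # GP vs emergency first presentation
    gp_accuracy: float = 0.9               # P(GP referral matches true comparison)
    gp_cost_mean: float = 100.0
    gp_cost_sd: float = 20.0
    ed_cost: float = 1000.0

    # -- adjudication ----------------------------------------------------
    accept_rate_acute: float = 0.90
    accept_rate_chronic: float = 0.60
    accept_rate_mental: float = 0.40
    claims_processing_capacity: int = 15   # claims adjudicated per step

    # -- treatment -------------------------------------------------------
    treatment_capacity: int = 1000
    capacity_variation_enabled: bool = False
    treatment_cost_mean: float = 100.0
    treatment_cost_sd: float = 20.0
    treatment_denial_rate: float = 0.05
    recovery_rate: float = 0.05            # fraction of health gap closed per step
    treatment_noise_amplitude: float = 1.0  # +/- health units of per-step noise

    # -- wage replacement ------------------------------------------------
    wage_replacement_fraction: float = 0.80
    steps_per_year: int = 50               # converts annual salary to per-step wage

    # -- return to work --------------------------------------------------
    rtw_policy: str = "neutral"            # discourage | neutral | encourage
    early_rtw_health_floor: float = 70.0
    occ_rehab_enabled: bool = False
    occ_rehab_cost: float = 10000.0
    occ_rehab_capacity: int = 10
    employer_readiness_max: float = 50.0   # per-attempt readiness ~ U[0, max]
    advertising_spend: float = 0.0         # currency per time-step
    advertising_readiness_gain: float = 50.0   # saturating maximum readiness gain
    advertising_half_saturation: float = 1000.0

    # -- disputes --------------------------------------------------------
    dispute_success_rate: float = 0.5
    dispute_duration: int = 5              # steps spent in dispute before resolution
    max_disputes_per_worker: int | None = None

    # -- termination -----------------------------------------------------
    max_claim_duration: int = 1000

    # -- arrivals and population -----------------------------------------
    arrival_rate: int = 10
    arrival_variation_enabled: bool = False
    injury_mix: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 / 3.0 for t in INJURY_TYPES}
    )
    salary_mean: float = 55000.0
    salary_sd: float = 10000.0
    entry_health_min: float = 20.0
    entry_trust_range: tuple[float, float] = (50.0, 100.0)
    entry_satisfaction_range: tuple[float, float] = (50.0, 100.0)
    entry_fight_range: tuple[float, float] = (0.0, 100.0)
    responsiveness_mean: float = 0.6
    responsiveness_sd: float = 0.3
    expectation_wait_mean: float = 35.0
    expectation_wait_sd: float = 10.0
    memory_span: int = 300

    # -- waitlist effect at the workplace --------------------------------
    waitlist_drift_mean: float = 0.0
    waitlist_drift_sd: float = 0.05

    # -- psychology ------------------------------------------------------
    psych_deltas: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PSYCH_DELTAS)
    )

    # -- optional shocks (minimal semantics) -----------------------------
    mistrust_contagion_enabled: bool = False
    mistrust_contagion_rate: float = 0.01
    mass_incident_step: int | None = None
    mass_incident_size: int = 0


@dataclass
class SimulationConfig:
    """One simulation run: horizon, seed, output path and levers."""

    n_steps: int = 2000
    seed: int = 0
    output: str | None = None
    levers: PolicyLevers = field(default_factory=PolicyLevers)


def _check_prob(violations: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        violations.append(f"{name}={value!r} must be a probability in [0, 1]")


def _check_nonneg(violations: list[str], name: str, value: float) -> None:
    if value < 0:
        violations.append(f"{name}={value!r} must be >= 0")


def _check_scale(violations: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        violations.append(f"{name}={value!r} must be in [0, 100]")


def validate_levers(levers: PolicyLevers) -> list[str]:
    """Return a list of invariant violations (empty iff the levers are valid).

    Violations are data, not exceptions: each entry names the offending
    field, its value and the constraint it breaks.
    """
    v: list[str] = []
    for name in (
        "p_gp_first",
        "gp_accuracy",
        "accept_rate_acute",
        "accept_rate_chronic",
        "accept_rate_mental",
        "treatment_denial_rate",
        "wage_replacement_fraction",
        "dispute_success_rate",
        "recovery_rate",
        "mistrust_contagion_rate",
    ):
        _check_prob(v, name, getattr(levers, name))
    for name in (
        "gp_cost_mean",
        "gp_cost_sd",
        "ed_cost",
        "claims_processing_capacity",
        "treatment_capacity",
        "treatment_cost_mean",
        "treatment_cost_sd",
        "treatment_noise_amplitude",
        "occ_rehab_cost",
        "occ_rehab_capacity",
        "advertising_spend",
        "advertising_readiness_gain",
        "max_claim_duration",
        "arrival_rate",
        "salary_mean",
        "salary_sd",
        "expectation_wait_mean",
        "expectation_wait_sd",
        "dispute_duration",
        "memory_span",
        "mass_incident_size",
        "steps_per_year",
    ):
        _check_nonneg(v, name, getattr(levers, name))
    for name in ("claim_threshold", "early_rtw_health_floor", "entry_health_min",
                 "employer_readiness_max"):
        _check_scale(v, name, getattr(levers, name))
    if levers.advertising_half_saturation <= 0:
        v.append(
            f"advertising_half_saturation={levers.advertising_half_saturation!r} "
            "must be > 0"
        )
    if levers.steps_per_year < 1:
        v.append(f"steps_per_year={levers.steps_per_year!r} must be >= 1")
    if levers.rtw_policy not in RTW_POLICIES:
        v.append(
            f"rtw_policy={levers.rtw_policy!r} must be one of {RTW_POLICIES}"
        )
    if set(levers.injury_mix) != set(INJURY_TYPES):
        v.append(
            f"injury_mix keys {sorted(levers.injury_mix)} must be exactly "
            f"{sorted(INJURY_TYPES)}"
        )
    else:
        total = sum(levers.injury_mix.values())
        if abs(total - 1.0) > 1e-9:
            v.append(f"injury_mix={levers.injury_mix!r} must sum to 1 (got {total})")
        if any(p < 0 for p in levers.injury_mix.values()):
            v.append(f"injury_mix={levers.injury_mix!r} has negative entries")
    for rng_name in ("entry_trust_range", "entry_satisfaction_range",
                     "entry_fight_range"):
        lo, hi = getattr(levers, rng_name)
        if not (0.0 <= lo <= hi <= 100.0):
            v.append(f"{rng_name}={(lo, hi)!r} must satisfy 0 <= lo <= hi <= 100")
    if not (-1.0 <= levers.responsiveness_mean <= 1.0):
        v.append(
            f"responsiveness_mean={levers.responsiveness_mean!r} must be in [-1, 1]"
        )
    if levers.responsiveness_sd < 0:
        v.append(f"responsiveness_sd={levers.responsiveness_sd!r} must be >= 0")
    if levers.max_disputes_per_worker is not None and levers.max_disputes_per_worker < 0:
        v.append(
            f"max_disputes_per_worker={levers.max_disputes_per_worker!r} must be >= 0"
        )
    unknown_events = set(levers.psych_deltas) - set(DEFAULT_PSYCH_DELTAS)
    if unknown_events:
        v.append(f"psych_deltas has unknown event tags {sorted(unknown_events)}")
    return v


_LEVER_FIELDS = {f.name: f for f in dataclasses.fields(PolicyLevers)}
_SIM_FIELDS = {"n_steps", "seed", "output", "levers"}


def _coerce_lever(name: str, value: Any) -> Any:
    """Light coercion of YAML scalars/collections into lever field types."""
    if name == "injury_mix":
        if not isinstance(value, dict):
            raise ConfigError(f"injury_mix must be a mapping, got {value!r}")
        return {str(k): float(p) for k, p in value.items()}
    if name == "psych_deltas":
        if not isinstance(value, dict):
            raise ConfigError(f"psych_deltas must be a mapping, got {value!r}")
        out = {}
        for k, pair in value.items():
            if not isinstance(pair, (list, tuple)) or len(pair) != 2:
                raise ConfigError(
                    f"psych_deltas[{k!r}] must be [trust_delta, satisfaction_delta]"
                )
            out[str(k)] = (float(pair[0]), float(pair[1]))
        return out
    if name.endswith("_range"):
        if not isinstance(value, (list, tuple)) or len(value) != 2:
            raise ConfigError(f"{name} must be a [low, high] pair, got {value!r}")
        return (float(value[0]), float(value[1]))
    return value


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a simulation config from a YAML file.

    An empty file yields the all-defaults configuration.  Unknown keys
    (at top level or inside ``levers:``) and invariant violations raise
    :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a nested dict."""
    unknown = set(raw) - _SIM_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    lever_raw = raw.get("levers") or {}
    if not isinstance(lever_raw, dict):
        raise ConfigError("'levers' must be a mapping")
    unknown = set(lever_raw) - set(_LEVER_FIELDS)
    if unknown:
        raise ConfigError(f"unknown lever names: {sorted(unknown)}")
    levers = PolicyLevers(
        **{k: _coerce_lever(k, v) for k, v in lever_raw.items()}
    )
    violations = validate_levers(levers)
    if violations:
        raise ConfigError("invalid levers: " + "; ".join(violations))
    n_steps = int(raw.get("n_steps", 2000))
    if n_steps < 1:
        raise ConfigError(f"n_steps={n_steps} must be >= 1")
    return SimulationConfig(
        n_steps=n_steps,
        seed=int(raw.get("seed", 0)),
        output=raw.get("output"),
        levers=levers,
    )


def serialize_config(config: SimulationConfig) -> str:
    """Serialize a config to YAML text that round-trips through load."""
    levers = dataclasses.asdict(config.levers)
    for name, value in list(levers.items()):
        if isinstance(value, tuple):
            levers[name] = list(value)
    levers["psych_deltas"] = {
        k: list(pair) for k, pair in levers["psych_deltas"].items()
    }
    doc = {
        "n_steps": config.n_steps,
        "seed": config.seed,
        "output": config.output,
        "levers": levers,
    }
    return yaml.safe_dump(doc, sort_keys=True)


def accept_rate_for(levers: PolicyLevers, injury_type: str) -> float:
    """Base claim-acceptance probability for an injury type."""
    return {
        "acute_physical": levers.accept_rate_acute,
        "chronic_physical": levers.accept_rate_chronic,
        "mental_health": levers.accept_rate_mental,
    }[injury_type]
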