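# worksim

An agent-based policy simulator for a no-fault workers' compensation
scheme. Injured workers flow through triage, claim lodgement,
adjudication, disputes, treatment and return-to-work (RTW) under a set
of observer-adjustable policy levers, and the simulator tracks the
system-level consequences: how many workers are in the scheme, what
they cost, how long their claims last, and how much trust and
satisfaction they retain.

It is written for scheme managers, policy analysts and health-system
modellers who want to compare candidate policy settings — claim
acceptance thresholds, administrative and treatment capacities,
early-RTW promotion, occupational rehabilitation support, advertising,
benefit termination rules — *before* trying them on real injured
workers. Outputs are deliberately uncalibrated to any real scheme's
finances: compare conditions against each other, not against reality.

## The model

Time advances in discrete, uncalibrated steps. Each step, a cohort of
newly injured workers (default 10) enters with individual attributes:

- health, trust, satisfaction and an appetite for fighting
  unfavourable decisions, each on a 0–100 point scale;
- a responsiveness-to-treatment multiplier ρ ∈ [−1, +1];
- an injury type (acute physical, chronic physical, mental health);
- a salary (lognormal, mean $55k, sd $10k);
- an expected claim-processing wait (≈ 35 steps) and a bounded event
  memory (up to 300 steps).

Workers first present to a GP (probability 0.5, cost ≈ $100) or an
emergency ward (cost $1000). A worker assessed below the claim
threshold (default 95 health points) is sent to claim lodgement; GPs
misdiagnose with probability 0.1 and send unfit workers back to the
workplace, which costs them trust. Lodged claims queue FIFO against an
administrative capacity and are accepted at injury-type base rates —
90% acute, 60% chronic, 40% mental health. Denied workers dispute with
probability

    p(dispute) = (fight / 100) · (1 − trust / 100),

otherwise they give up and leave. Disputes erode trust and
satisfaction while they run and succeed at a configurable rate.

Treatment closes a fraction of the health gap each step:

    h ← clamp(h + 0.05 · ρ · (100 − h) + ε, 0, 100),   ε ~ U(−1, 1)

so recovery is fast early and slows near full health; each delivered
service costs ≈ $100 (sd $20), and workers on accepted claims accrue
wage replacement at 80% of salary. Treatment can be denied
(disputable, trust-eroding). A worker reaching the claim threshold
makes a *full* RTW. Under the `encourage` policy, workers at or above
an early-RTW health floor (default 70) instead attempt a return
through their employer: if the employer's readiness covers the health
shortfall — optionally bridged by a $10,000 occupational
rehabilitation support — the worker makes a *partial* RTW on pro-rata
wage replacement (a 75%-fit worker costs 25% × 0.8 of salary);
otherwise the attempt is a *failed* RTW and the worker returns to
treatment. Claims whose duration surpasses the maximum limit are
terminated.

Costs are accounted exactly (integer cents) in per-worker and
system-level ledgers; GP/emergency costs reach the system ledger only
if the claim is later accepted.

## Worked example

```bash
python examples/baseline_run.py
```

prints (seed 42, 300 steps, default levers):

```
steps run:            300
workers in system:    620
  in treatment:       577
  awaiting adjudication: 10
mean health:          73.9 / 100
mean trust:           52.8 / 100
mean satisfaction:    69.8 / 100
full RTWs so far:     1303
disputes so far:      1650
mean claim duration at exit: 70.0 steps
cumulative wage cost:      $120,764,382
cumulative treatment cost: $12,577,415
cumulative total cost:     $134,405,837
```

Reading the numbers: ~3000 workers entered over 300 steps and about
620 remain in the scheme, mostly in treatment — the census the
adjudication and treatment capacities can sustain. The average claim
that has closed lasted 70 steps. Costs are dominated by wage
replacement (80% of salary while fully off work), an order of
magnitude above treatment costs.

The other examples contrast policy conditions
(`examples/policy_matrix.py`) and show the dispute/trust feedback
loop (`examples/dispute_dynamics.py`).

## Command line

```bash
worksim run --config examples/scheme_config.yaml --out run.csv
worksim experiment --reps 30 --steps 2000 --seed 42 --out results.csv
worksim plot --in results.csv --out figs/
```

`worksim experiment` defaults to the shipped six-condition matrix:
RTW policy ∈ {discourage, neutral, encourage} × occupational rehab
∈ {off, on}, with replicate seeds paired across conditions.

## Configuration schema

A config is a YAML file with optional `n_steps` (default 2000),
`seed`, `output`, and a flat `levers:` mapping. Unknown keys are
errors. Every lever, with its default:

| Lever | Default | Meaning |
|---|---|---|
| `claim_threshold` | 95 | health points below which an injury is claim-eligible (and above which a worker is recovered) |
| `p_gp_first` | 0.5 | probability of first presenting to a GP rather than emergency |
| `gp_accuracy` | 0.9 | probability the GP referral matches the true threshold comparison |
| `gp_cost_mean` / `gp_cost_sd` | 100 / 20 | GP consultation cost ($, truncated normal) |
| `ed_cost` | 1000 | emergency visit cost ($, fixed) |
| `accept_rate_acute` | 0.90 | claim acceptance probability, acute physical |
| `accept_rate_chronic` | 0.60 | claim acceptance probability, chronic physical |
| `accept_rate_mental` | 0.40 | claim acceptance probability, mental health |
| `claims_processing_capacity` | 15 | claims adjudicated per step |
| `treatment_capacity` | 1000 | workers treatable per step |
| `capacity_variation_enabled` | false | intermittent shortage shocks (capacity halves on 10% of steps) |
| `treatment_cost_mean` / `treatment_cost_sd` | 100 / 20 | cost per delivered treatment service ($) |
| `treatment_denial_rate` | 0.05 | probability a treatment step is denied |
| `recovery_rate` | 0.05 | fraction of the health gap closed per treated step |
| `treatment_noise_amplitude` | 1.0 | half-width of the per-step uniform health noise |
| `wage_replacement_fraction` | 0.80 | fraction of salary replaced while off work |
| `steps_per_year` | 50 | converts annual salary to a per-step wage |
| `rtw_policy` | neutral | `discourage` / `neutral` / `encourage` early RTW through the employer |
| `early_rtw_health_floor` | 70 | health at which encouraged workers attempt an employer RTW |
| `occ_rehab_enabled` | false | occupational rehabilitation support switch |
| `occ_rehab_cost` | 10000 | $ charged to the system per supported worker |
| `occ_rehab_capacity` | 10 | workers supportable per step |
| `employer_readiness_max` | 50 | per-attempt employer readiness ~ U[0, max] |
| `advertising_spend` | 0 | $ per step, raises employer readiness (saturating) |
| `advertising_readiness_gain` | 50 | maximum readiness gain from advertising |
| `advertising_half_saturation` | 1000 | spend at which half the maximum gain is reached |
| `dispute_success_rate` | 0.5 | probability a dispute is upheld for the worker |
| `dispute_duration` | 5 | steps a dispute takes to resolve |
| `max_disputes_per_worker` | none | optional safety cap on repeat disputes |
| `max_claim_duration` | 1000 | steps before an accepted claim's benefits terminate |
| `arrival_rate` | 10 | newly injured workers per step |
| `arrival_variation_enabled` | false | ±1 random-walk step in the rate every 50 steps |
| `injury_mix` | ⅓ / ⅓ / ⅓ | entry probabilities over the three injury types |
| `salary_mean` / `salary_sd` | 55000 / 10000 | lognormal salary parameters ($/year) |
| `entry_health_min` | 20 | entry health ~ U[min, claim_threshold) |
| `entry_trust_range` | [50, 100] | entry trust ~ uniform |
| `entry_satisfaction_range` | [50, 100] | entry satisfaction ~ uniform |
| `entry_fight_range` | [0, 100] | entry fight appetite ~ uniform |
| `responsiveness_mean` / `responsiveness_sd` | 0.6 / 0.3 | truncated-normal responsiveness on [−1, 1] |
| `expectation_wait_mean` / `expectation_wait_sd` | 35 / 10 | expected claim-processing wait (steps) |
| `memory_span` | 300 | event-memory capacity (steps) |
| `waitlist_drift_mean` / `waitlist_drift_sd` | 0.0 / 0.05 | per-step health drift while waiting at the workplace or working part-time, applied as max(0, N(μ, σ)) |
| `psych_deltas` | see docs | trust/satisfaction point changes per event |
| `mistrust_contagion_enabled` | false | story-sharing trust contagion toggle |
| `mistrust_contagion_rate` | 0.01 | per-step contagion probability |
| `mass_incident_step` / `mass_incident_size` | none / 0 | one-off extra injury cohort |

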