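# Methods

## Model overview and assumptions

worksim is a discrete-time, agent-based model of a no-fault workers'
compensation scheme. One time-step is deliberately uncalibrated to
calendar time; `steps_per_year = 50` exists only to convert annual
salaries into per-step wage payments, making a 2000-step run a
multi-year horizon. All dollar outputs are therefore internally
consistent but not calibrated to any real scheme — the model supports
*comparisons between policy settings*, not forecasts.

Each live worker occupies exactly one position in the scheme's state
chart: GP, emergency, workplace check, claim lodgement, accepted
(awaiting treatment), treatment, dispute, RTW pool, or exited. A
simulation step executes a fixed phase order:

1. spawn the arriving cohort,
2. GP / emergency assessments,
3. workplace re-checks,
4. claim adjudication (FIFO, capacity-limited),
5. dispute resolutions,
6. treatment (admissions, denials, health updates, cost and wage accrual),
7. return-to-work attempts,
8. termination checks,
9. psychology updates (expectation waits, optional contagion),
10. metrics snapshot.

The underlying state chart fixes the topology of worker movement but
not the order in which simultaneous transitions fire; the phase order
above (left-to-right through the chart) is part of this model's
definition. Two consequences worth knowing: a claim lodged in step *t*
is adjudicated at the earliest in step *t* + 1 (assessment takes time
even with spare capacity), while a dispute entered during adjudication
is already "in dispute" for that step's resolution phase — with
`dispute_duration = 1` it can resolve the same step it was raised.

## Key mechanisms

**Triage and misdiagnosis.** Workers present to a GP with probability
`p_gp_first`, else to emergency. The GP's referral matches the true
health-vs-threshold comparison with probability `gp_accuracy` (default
0.9); the emergency pathway applies the same comparison without error,
since misdiagnosis is attributed to GPs only. GP/emergency costs are
recorded against the worker and transferred to the system ledger only
when a claim is accepted.

**Recovery under treatment.** health ← clamp(h + r·ρ·(100 − h) + ε)
with recovery rate r = 0.05, individual responsiveness ρ ∈ [−1, 1]
and ε ~ U(−amplitude, +amplitude). The noiseless trajectory is the
geometric-gap curve h(t) = 100 − (100 − h₀)(1 − rρ)^t, which the test
suite verifies to 1e-9 and, with noise on, as a Monte-Carlo mean.
Negative responders exist (about 2% at the default truncated-normal
ρ ~ N(0.6, 0.3²) on [−1, 1]); they deteriorate under treatment and
are the main clients of the claim-duration termination rule.

**Disputes.** An unfavourable decision is disputed with probability
(fight/100)(1 − trust/100) — the minimal form that is strictly
increasing in the appetite to fight and strictly decreasing in trust.
Trust/satisfaction changes are a configurable per-event delta table
(claim denied −5 trust; treatment denied −5; sent back from the
workplace −2; each step in dispute −1/−1; each step waiting beyond the
worker's expectation −1; dispute lost −5/−5; dispute won +2), always
clamped to [0, 100]. Directions are fixed by the model narrative;
magnitudes are levers. A successful treatment dispute returns the
worker to treatment with priority re-admission (our reading of
"directly back" that still respects the treatment-capacity bound); a
failed one re-enters through the claim-acceptance pathway.

**Return to work.** Full RTW opens at the claim threshold. Under
`encourage`, workers at or above the early-RTW floor attempt a return
through their employer: per-attempt readiness ~ U[0, 50], raised by a
saturating advertising gain g(s) = 50·s/(s + 1000), must cover the
health shortfall to the threshold; occupational rehabilitation (when
enabled, up to `occ_rehab_capacity` workers/step, $10,000 charged once
per supported worker) bridges any remaining gap. Partial returners
accrue pro-rata wage replacement (fitness credit = health/100), occupy
no treatment capacity, and convert to full RTW if their health ever
reaches the threshold. Under `neutral` and `discourage` there is no
employer routing; at shipped defaults those two settings are
behaviourally identical and, with paired seeds, produce identical
runs — the distinction is retained because the promotion lever has
three nominal settings and custom configurations (e.g. a
policy-dependent floor) can separate them.

## Calibration of the at-work drift

Health while waiting at the workplace or working part-time drifts by
max(0, N(μ_w, σ_w)) per step. This "waitlist effect" is the single
most consequential free parameter in the model: it sets how quickly a
partially returned worker finishes recovering *away from treatment*.
The shipped default is μ_w = 0, σ_w = 0.05 (≈ 0.02 health/step
effective), an order of magnitude below even a slow responder's
treatment gain. Under this calibration, encouraging early RTW through
the employer parks workers at work on long-running claims: final-step
worker counts, claim durations, wage-replacement costs and total
system costs are all highest under encourage + occ-rehab and lowest
under the treatment-recovery settings, and total-cost orderings follow
claim-duration orderings — the qualitative pattern this simulator is
designed to exhibit at its defaults. A materially faster drift (e.g.
effective ≳ 0.1/step) erases and eventually reverses the cost
ordering, because the per-step wage discount of partial RTW then
outweighs the duration penalty; the parameter is config-exposed for
exactly this kind of sensitivity analysis.

Other defaults chosen where the narrative names a lever without a
value: `gp_accuracy` 0.9, `dispute_success_rate` 0.5,
`dispute_duration` 5, `treatment_denial_rate` 0.05 ("occasionally"),
`claims_processing_capacity` 15 (slightly above the default arrival
rate, so queues form under load but do not explode),
`treatment_capacity` 1000 (near-binding at the steady-state census),
`max_claim_duration` 1000 (termination rare but reachable in a
2000-step run), equal `injury_mix`, and uniform entry distributions on
the 100-point scales (health on [20, threshold), trust and
satisfaction on [50, 100], fight on [0, 100]).

## Accounting

All costs are held as integer cents, so ledger conservation is exact,
not float-tolerant: at any step, each system-ledger category equals
the sum of the matching system-charged category over all workers ever
spawned, with advertising charged to its own system-only category.
Wage cents are rounded per worker-step; the cached full-incapacity
wage and the pro-rata partial wage use the same rounding rule.

## What the synthetic population does and does not emulate

Workers are synthesized from the stated entry distributions
(positively skewed lognormal salary re-parameterised to mean $55k /
sd $10k; 100-point psychological scales; truncated-normal
responsiveness). The generator deliberately omits demographic
covariates (age, sex, industry), injury-type-specific entry health,
within-worker correlation between attributes, and any real claims
data. Passing tests therefore demonstrate internal mechanistic
consistency — parameter echoes, conservation, directional policy
contrasts — not predictive validity for any real scheme.

## Numerical and procedural choices

- Randomness flows from a single seeded generator per run; identical
  seeds give byte-identical CSV outputs. Replicate seeds in the
  experiment runner depend only on the replicate index, so every
  condition sees the same worker-attribute stream (paired-seed
  variance reduction).
- The RTW-pool drift is drawn as one vectorised normal per step (in
  pool order); all other draws are per-worker scalars in a fixed
  iteration order.
- Queue discipline is FIFO everywhere; dispute-won treatment returns
  pre-empt the accepted queue.
- Capacity shocks (when enabled) halve both adjudication and
  treatment service capacity on a random 10% of steps.
- Means over empty groups are reported as missing (None/NaN), never 0.
- Degenerate inputs: zero arrival rate yields a fixed point (only the
  clock advances); `max_claim_duration = inf` disables termination;
  probability levers at 0/1 are exact, not approximate.

## Test problem sizes

Distributional checks use 100,000 draws (triage split, injury mix,
salary moments) or 10,000–50,000 (acceptance rates, cost means,
Monte-Carlo recovery); conservation is audited across a full
2000-step default run; the directional policy comparison runs the six
policy conditions for the full 2000-step horizon with two paired
replicates per condition, a scaled-down replicate count of the
30-replicate design the runner ships by default.

## Known limitations

- Neutral and discourage RTW settings coincide at shipped defaults
  (above).
- The treatment-denial → mean-health knock-on is measured over the
  scheme's fill-up phase; at long horizons the census average can move
  the other way for composition reasons (denials and disputes detain
  nearly recovered, high-health workers in the system, and negative
  responders are harmed *less* when denied), even though every denied
  worker individually recovers more slowly.
- Partial returners cannot relapse; employers have no memory across
  attempts; dispute legal costs are not modelled; there is no
  within-step concurrency beyond the documented phase order.
- The mass-incident and mistrust-contagion toggles are minimal
  placeholders (a one-off extra cohort; copying a lower trust value
  from a random same-stage peer) and are off by default.
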