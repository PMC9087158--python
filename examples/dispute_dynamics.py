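"""How treatment denial feeds the dispute loop and erodes trust.

Runs the same 200-step scheme twice — once with treatment essentially
never denied, once with half of all treatment steps denied — and
contrasts dispute volumes, trust and health.
"""

import numpy as np

from worksim import PolicyLevers, SimulationConfig, run_simulation

for denial_rate in (0.0, 0.5):
    levers = PolicyLevers(treatment_denial_rate=denial_rate)
    config = SimulationConfig(n_steps=200, seed=11, levers=levers)
    series, state = run_simulation(config)
    final = series[-1]
    run_avg_health = np.mean(
        [m.mean_health for m in series if m.mean_health is not None]
    )
    print(f"treatment_denial_rate = {denial_rate}")
    print(f"  disputes raised:        {final.n_disputes}")
    print(f"  mean trust (final):     {final.mean_trust:.1f}")
    print(f"  mean trust | accepted:  {final.mean_trust_accepted:.1f}")
    print(f"  mean health (run avg):  {run_avg_health:.1f}")
    print()

# What to look for: denying treatment triggers the dispute decision
# p = (fight/100) x (1 - trust/100), so denials compound — each one
# erodes trust, which makes the next unfavourable decision more likely
# to be disputed.  Under heavy denial the dispute count explodes,
# population trust falls, and the run-average health of workers in the
# system is lower because recovery keeps stalling.
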