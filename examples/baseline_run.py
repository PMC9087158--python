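"""Run the scheme at its default policy settings and read the monitors.

Builds the default configuration (10 injured workers arriving per
time-step, 50/50 GP/emergency triage, 90/60/40% acceptance by injury
type, treatment closing 5% of the health gap per step), runs 300
time-steps and prints the headline monitors.
"""

from worksim import SimulationConfig, run_simulation

config = SimulationConfig(n_steps=300, seed=42)
series, state = run_simulation(config)
final = series[-1]

print(f"steps run:            {final.t}")
print(f"workers in system:    {final.n_in_system}")
print(f"  in treatment:       {final.n_treatment}")
print(f"  awaiting adjudication: {final.n_claim_lodgement}")
print(f"mean health:          {final.mean_health:.1f} / 100")
print(f"mean trust:           {final.mean_trust:.1f} / 100")
print(f"mean satisfaction:    {final.mean_satisfaction:.1f} / 100")
print(f"full RTWs so far:     {final.n_full_rtw}")
print(f"disputes so far:      {final.n_disputes}")
print(f"mean claim duration at exit: {final.mean_claim_duration_at_exit:.1f} steps")
print(f"cumulative wage cost:      ${final.cum_wage_cost:,.0f}")
print(f"cumulative treatment cost: ${final.cum_treatment_cost:,.0f}")
print(f"cumulative total cost:     ${final.cum_total_cost:,.0f}")

# What to look for: the system fills toward a steady census of several
# hundred workers; most exit via full return-to-work after a few dozen
# treated steps; costs are dominated by wage replacement (80% of salary
# while off work).  Absolute dollar figures are deliberately
# uncalibrated — compare them between policy settings, not to reality.
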