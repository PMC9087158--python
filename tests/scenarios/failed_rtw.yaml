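# Encouraged early return: the employer is not ready to cover the
# health shortfall and occupational rehab is off, so the attempt is a
# failed RTW and the worker stays in treatment.
worker:
  id: 0
  stage: treatment
  health: 80.0
  responsiveness: 0.6
  accepted: accepted
  claim_active_since: 0
levers:
  arrival_rate: 0
  rtw_policy: encourage
  early_rtw_health_floor: 70.0
  treatment_denial_rate: 0.0
  treatment_noise_amplitude: 0.0
  occ_rehab_enabled: false
n_steps: 1
strict: true
draws:
  random: [0.9]             # treatment denial draw (not denied)
  normal: [100.0]           # treatment service cost
  uniform: [5.0]            # employer readiness 5 < shortfall ~14.4
expected_transitions:
  - failed_rtw
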