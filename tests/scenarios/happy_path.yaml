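# GP -> lodgement -> accepted -> treatment -> full RTW -> exit,
# fully determined by forced draws and degenerate lever settings.
worker:
  id: 0
  stage: gp
  health: 90.0
  responsiveness: 1.0
levers:
  arrival_rate: 0
  gp_accuracy: 1.0
  accept_rate_acute: 1.0
  treatment_denial_rate: 0.0
  treatment_noise_amplitude: 0.0
  recovery_rate: 0.9        # one treated step lifts 90 -> 99, past the threshold
n_steps: 3
strict: true
draws:
  # normal: GP consultation cost, treatment service cost
  normal: [100.0, 100.0]
  # random: GP accuracy draw, adjudication draw, treatment denial draw
  random: [0.0, 0.0, 0.9]
expected_transitions:
  - referred_to_lodgement
  - claim_accepted
  - admitted_to_treatment
  - full_rtw_pool
  - full_rtw
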