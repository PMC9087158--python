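# Claim denied -> worker disputes -> dispute upheld -> back into the
# lodgement queue to try again.
worker:
  id: 0
  stage: claim_lodgement
  trust: 0.0
  fight_appetite: 100.0     # dispute probability (fight/100)(1-trust/100) = 1
levers:
  arrival_rate: 0
  accept_rate_acute: 0.0
  dispute_success_rate: 1.0
  dispute_duration: 1
# step 0: the freshly lodged claim waits; step 1: denied -> dispute ->
# resolved in the worker's favour -> back into the queue
n_steps: 2
strict: true
draws:
  # random: adjudication draw (denied), dispute decision, dispute resolution
  random: [0.5, 0.0, 0.0]
expected_transitions:
  - dispute_claim
  - dispute_won_relodge
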