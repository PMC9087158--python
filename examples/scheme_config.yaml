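# Example simulation config for `worksim run --config scheme_config.yaml`.
# Any omitted lever takes its documented default; unknown keys are errors.
n_steps: 500
seed: 42
levers:
  arrival_rate: 10
  claim_threshold: 95
  rtw_policy: encourage
  early_rtw_health_floor: 70
  occ_rehab_enabled: true
  occ_rehab_capacity: 10
  treatment_denial_rate: 0.05
  advertising_spend: 100.0
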