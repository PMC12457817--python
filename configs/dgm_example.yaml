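# Mechanism specification for `causalcf generate`: shipped defaults with
# field-level overrides.
dgm_name: simple-1
n: 500
seed: 42
overrides:
  outcome_effect: 0.25
  residual_sd: 0.8
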