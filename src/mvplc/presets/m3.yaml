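# M3: ultrasound modelled as an imperfect gold standard (informative
# accuracy priors); conditional independence between all three tests.
tests:
  - name: ultrasound
    categories: 2
  - name: ddimer
    categories: 2
  - name: wells
    categories: 3
    labels: {L: 1, M: 2, H: 3}
perfect_gs: []
dependence: none
anchor_test: ultrasound
priors:
  tests:
    ultrasound:
      se_interval: [0.49, 0.94]
      sp_interval: [0.82, 0.99]
    wells:
      mu_mean: 0.0
      mu_sd: 1.0
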