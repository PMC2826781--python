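# Grade 3/4 adverse-event rates with (post) and without (pre) primary
# G-CSF prophylaxis in the intervention arm, and the comparator arm's
# observed rates from the same source study.
ae_rates_pre:
  febrile_neutropenia: 0.246
  stomatitis: 0.064
  diarrhea: 0.070
  infection: 0.028
ae_rates_post:
  febrile_neutropenia: 0.065
  stomatitis: 0.026
  diarrhea: 0.026
  infection: 0.017
ae_rates_fac:
  febrile_neutropenia: 0.023
  stomatitis: 0.027
  diarrhea: 0.008
  infection: 0.018
# per-patient cost of G-CSF before every cycle; null -> per-event
# acquisition cost x 6 cycles
gcsf_cost_all_cycles: null
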