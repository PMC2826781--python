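# One-way sensitivity scenario catalogue for the base-case model.
scenarios:
  - name: "Adverse event rates (GEICAM study)"
    perturbations:
      - {path: "arms.TAC.ae_rates.febrile_neutropenia", op: set, value: 0.246}
      - {path: "arms.TAC.ae_rates.stomatitis", op: set, value: 0.064}
      - {path: "arms.TAC.ae_rates.diarrhea", op: set, value: 0.070}
      - {path: "arms.TAC.ae_rates.infection", op: set, value: 0.028}
      - {path: "arms.FAC.ae_rates.febrile_neutropenia", op: set, value: 0.023}
      - {path: "arms.FAC.ae_rates.stomatitis", op: set, value: 0.027}
      - {path: "arms.FAC.ae_rates.diarrhea", op: set, value: 0.008}
      - {path: "arms.FAC.ae_rates.infection", op: set, value: 0.018}

  - name: "Adverse event rates increased by 25%"
    perturbations:
      - {path: "arms.*.ae_rates.*", op: scale, value: 1.25}
  - name: "Adverse event rates decreased by 25%"
    perturbations:
      - {path: "arms.*.ae_rates.*", op: scale, value: 0.75}
  - name: "Adverse event rates in TAC increased by 25%"
    perturbations:
      - {path: "arms.TAC.ae_rates.*", op: scale, value: 1.25}
  - name: "Adverse event rates in TAC decreased by 25%"
    perturbations:
      - {path: "arms.TAC.ae_rates.*", op: scale, value: 0.75}
  - name: "Rates of febrile neutropenia increased by 25%"
    perturbations:
      - {path: "arms.*.ae_rates.febrile_neutropenia", op: scale, value: 1.25}
  - name: "Rates of febrile neutropenia decreased by 25%"
    perturbations:
      - {path: "arms.*.ae_rates.febrile_neutropenia", op: scale, value: 0.75}

  - name: "Increased probability of relapse by 25% in TAC arm"
    perturbations:
      - {path: "arms.TAC.n_recurrences", op: scale, value: 1.25}
  - name: "Decreased probability of relapse by 25% in TAC arm"
    perturbations:
      - {path: "arms.TAC.n_recurrences", op: scale, value: 0.75}

  - name: "Follow-up cost: no recurrence +25%, metastatic -25%"
    perturbations:
      - {path: "costs.followup_no_recurrence.*", op: scale, value: 1.25}
      - {path: "costs.followup_metastatic_annual", op: scale, value: 0.75}
  - name: "Follow-up cost: no recurrence -25%, metastatic +25%"
    perturbations:
      - {path: "costs.followup_no_recurrence.*", op: scale, value: 0.75}
      - {path: "costs.followup_metastatic_annual", op: scale, value: 1.25}

  - name: "Recurrence at 25%"
    perturbations:
      - {path: "transition.percent_met_relapse", op: set, value: 0.25}
  - name: "Recurrence at 100%"
    perturbations:
      - {path: "transition.percent_met_relapse", op: set, value: 1.0}

  - name: "Equate utility value"
    perturbations:
      - {path: "utilities.disutility_tac", op: set, value: 0.0035}
  - name: "Lowest utility value"
    perturbations:
      - {path: "utilities.u_distant_range", op: set, value: [0.49, 0.49]}
  - name: "Highest utility value"
    perturbations:
      - {path: "utilities.u_distant_range", op: set, value: [0.65, 0.65]}

  - name: "Supportive care cost increased by 25%"
    perturbations:
      - {path: "costs.supportive_care_components.*.*.0", op: scale, value: 1.25}
  - name: "Supportive care cost decreased by 25%"
    perturbations:
      - {path: "costs.supportive_care_components.*.*.0", op: scale, value: 0.75}
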