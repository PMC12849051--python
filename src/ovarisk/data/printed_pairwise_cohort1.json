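{
  "comment": "Printed paired comparison between the two RMI 1 thresholds in cohort 1 (the only comparison recomputable from printed marginal counts: the thresholds are nested, so all discordance is 200-positive/250-negative). Deltas follow the comparator-minus-test convention with RMI1@250 as comparator. Other pairwise rows use common-subset sensitivities that printed counts do not determine.",
  "rmi1@200_vs_rmi1@250": {
    "n_common": 672,
    "n_cases": 47,
    "n_controls": 625,
    "delta_sensitivity": -6.4,
    "delta_sensitivity_ci": [-15.5, 2.7],
    "p_sensitivity": 0.25,
    "delta_specificity": 1.1,
    "delta_specificity_ci": [0.1, 2.1],
    "p_specificity": 0.02
  }
}
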