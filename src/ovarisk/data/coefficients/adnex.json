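{
  "model_id": "adnex",
  "version_label": "synthetic-approximation-1",
  "comment": "SYNTHETIC stand-in: the published ADNEX coefficients are not reprinted in the accuracy study this package replicates and could not be transcribed from the original model publication here. This set preserves the published functional form (multinomial logit, benign reference, predictors age, ln CA125, ln max lesion diameter, proportion solid, >10 locules, papillation count 0-4, acoustic shadows, ascites, oncology centre) with plausible-magnitude coefficients, and is swappable for a faithful transcription.",
  "strata": {
    "with_ca125": {
      "borderline": {"intercept": -7.5, "age": 0.02, "ln_ca125": 0.2, "ln_max_lesion_diameter": 0.6, "proportion_solid": 1.2, "more_than_10_locules": 0.4, "papillation_count": 0.4, "acoustic_shadows": -0.6, "ascites": 0.3, "oncology_centre": 0.4},
      "stage1": {"intercept": -10.0, "age": 0.03, "ln_ca125": 0.4, "ln_max_lesion_diameter": 0.9, "proportion_solid": 2.4, "more_than_10_locules": 0.3, "papillation_count": 0.3, "acoustic_shadows": -0.9, "ascites": 0.5, "oncology_centre": 0.5},
      "stage2_4": {"intercept": -12.0, "age": 0.05, "ln_ca125": 0.9, "ln_max_lesion_diameter": 0.5, "proportion_solid": 2.8, "more_than_10_locules": -0.3, "papillation_count": 0.2, "acoustic_shadows": -1.1, "ascites": 1.3, "oncology_centre": 0.7},
      "secondary_metastatic": {"intercept": -12.0, "age": 0.04, "ln_ca125": 0.5, "ln_max_lesion_diameter": 0.3, "proportion_solid": 2.2, "more_than_10_locules": 0.5, "papillation_count": -0.1, "acoustic_shadows": -1.0, "ascites": 1.1, "oncology_centre": 0.6}
    },
    "without_ca125": {
      "borderline": {"intercept": -6.9, "age": 0.02, "ln_max_lesion_diameter": 0.6, "proportion_solid": 1.2, "more_than_10_locules": 0.4, "papillation_count": 0.4, "acoustic_shadows": -0.6, "ascites": 0.3, "oncology_centre": 0.4},
      "stage1": {"intercept": -8.8, "age": 0.03, "ln_max_lesion_diameter": 0.9, "proportion_solid": 2.4, "more_than_10_locules": 0.3, "papillation_count": 0.3, "acoustic_shadows": -0.9, "ascites": 0.5, "oncology_centre": 0.5},
      "stage2_4": {"intercept": -9.3, "age": 0.05, "ln_max_lesion_diameter": 0.5, "proportion_solid": 2.8, "more_than_10_locules": -0.3, "papillation_count": 0.2, "acoustic_shadows": -1.1, "ascites": 1.3, "oncology_centre": 0.7},
      "secondary_metastatic": {"intercept": -10.5, "age": 0.04, "ln_max_lesion_diameter": 0.3, "proportion_solid": 2.2, "more_than_10_locules": 0.5, "papillation_count": -0.1, "acoustic_shadows": -1.0, "ascites": 1.1, "oncology_centre": 0.6}
    }
  },
  "transforms": {"ca125": "ln", "max_lesion_diameter": "ln"},
  "source_citation": "Functional form after Van Calster B et al. BMJ 2014;349:g5920 (ADNEX); numeric values are a synthetic approximation, see comment."
}
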