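{
  "model_id": "srrisk",
  "version_label": "synthetic-approximation-1",
  "comment": "SYNTHETIC stand-in: the published simple-rules-risk coefficients are not reprinted in the accuracy study this package replicates and could not be transcribed from the original model publication here. The functional form (logistic regression on the ten IOTA B/M feature indicators plus oncology-centre type) is as published; numeric values are plausible-magnitude placeholders, swappable for a faithful transcription.",
  "strata": {
    "all": {
      "intercept": -2.8,
      "oncology_centre": 0.9,
      "B1": -0.9, "B2": -0.8, "B3": -1.1, "B4": -0.9, "B5": -0.8,
      "M1": 1.7, "M2": 1.2, "M3": 1.5, "M4": 1.0, "M5": 1.3
    }
  },
  "transforms": {},
  "source_citation": "Functional form after Timmerman D et al. Am J Obstet Gynecol 2016;214:424-37 (simple rules risk); numeric values are a synthetic approximation, see comment."
}
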