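{
  "model_id": "roma",
  "version_label": "moore-2009-predictive-index",
  "strata": {
    "premenopausal": {"intercept": -12.0, "ln_he4": 2.38, "ln_ca125": 0.0626},
    "postmenopausal": {"intercept": -8.09, "ln_he4": 1.04, "ln_ca125": 0.732}
  },
  "transforms": {"he4": "ln", "ca125": "ln"},
  "source_citation": "Moore RG et al. A novel multiple marker bioassay utilizing HE4 and CA125 for the prediction of ovarian cancer in patients with a pelvic mass. Gynecol Oncol 2009;112:40-6."
}
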