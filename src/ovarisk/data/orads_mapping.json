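{
  "comment": "Approximate, documented rule table mapping IOTA-described exams to ORADS categories 1-5. Rules are evaluated in order; the first match wins. Category semantics: 1 normal ovary; 2 almost certainly benign (simple unilocular cyst < 10 cm); 3 low risk (smooth multilocular, shadowing dermoid-like lesion, or large unilocular cyst); 4 intermediate risk (any solid component or 1-3 papillary projections); 5 high risk (metastases, ascites with a solid lesion, or 4+ papillary projections). Binary reading downstream: positive iff category 4 or 5.",
  "rules": [
    {"when": {"lesion_present": false}, "category": "1", "note": "no adnexal lesion: normal ovary"},
    {"when": {"metastases": true}, "category": "5", "note": "peritoneal/omental deposits"},
    {"when": {"ascites": true, "solid": true}, "category": "5", "note": "solid lesion with ascites"},
    {"when": {"papillation_count_ge": 4}, "category": "5", "note": "4 or more papillary projections"},
    {"when": {"solid": true}, "category": "4", "note": "any solid component"},
    {"when": {"papillation_count_ge": 1}, "category": "4", "note": "1-3 papillary projections"},
    {"when": {"multilocular": true}, "category": "3", "note": "smooth multilocular cyst, no solid component"},
    {"when": {"acoustic_shadows": true}, "category": "3", "note": "shadowing, dermoid-like lesion"},
    {"when": {"max_lesion_diameter_ge": 100}, "category": "3", "note": "unilocular cyst 10 cm or larger"},
    {"when": {}, "category": "2", "note": "simple unilocular cyst under 10 cm"}
  ]
}
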