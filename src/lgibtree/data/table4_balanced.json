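{
  "provenance": "Balanced sensitivity/specificity LGIB rule (classification tree grown with prior LGIB probability 0.70; derivation-cohort per-clause tallies attached)",
  "default": "Not LGIB",
  "clauses": [
    {"field": "principal_dx",   "code": "562.12", "class": "LGIB", "n_correct": 71, "n_incorrect": 2},
    {"field": "secondary_dx",   "code": "578.1",  "class": "LGIB", "n_correct": 62, "n_incorrect": 94},
    {"field": "principal_dx",   "code": "578.1",  "class": "LGIB", "n_correct": 40, "n_incorrect": 20},
    {"field": "principal_dx",   "code": "578.9",  "class": "LGIB", "n_correct": 24, "n_incorrect": 17},
    {"field": "secondary_dx",   "code": "280.0",  "class": "LGIB", "n_correct": 22, "n_incorrect": 136},
    {"field": "secondary_dx",   "code": "211.3",  "class": "LGIB", "n_correct": 12, "n_incorrect": 39},
    {"field": "secondary_dx",   "code": "578.9",  "class": "LGIB", "n_correct": 9,  "n_incorrect": 24},
    {"field": "secondary_dx",   "code": "562.12", "class": "LGIB", "n_correct": 8,  "n_incorrect": 3},
    {"field": "principal_dx",   "code": "556.9",  "class": "LGIB", "n_correct": 6,  "n_incorrect": 4},
    {"field": "principal_proc", "code": "45.23",  "class": "LGIB", "n_correct": 6,  "n_incorrect": 22},
    {"field": "principal_dx",   "code": "558.9",  "class": "LGIB", "n_correct": 4,  "n_incorrect": 22},
    {"field": "secondary_dx",   "code": "562.10", "class": "LGIB", "n_correct": 5,  "n_incorrect": 96},
    {"field": "secondary_proc", "code": "45.23",  "class": "LGIB", "n_correct": 3,  "n_incorrect": 29},
    {"field": "secondary_dx",   "code": "556.9",  "class": "LGIB", "n_correct": 2,  "n_incorrect": 9}
  ],
  "default_counts": {"n_correct": 6160, "n_incorrect": 23}
}
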