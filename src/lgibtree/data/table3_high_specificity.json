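{
  "provenance": "High-specificity LGIB rule (classification tree grown with prior LGIB probability 0.20; derivation-cohort per-clause tallies attached)",
  "default": "Not LGIB",
  "clauses": [
    {"field": "principal_dx", "code": "562.12", "class": "LGIB", "n_correct": 71, "n_incorrect": 2},
    {"field": "secondary_dx", "code": "578.1",  "class": "LGIB", "n_correct": 62, "n_incorrect": 94},
    {"field": "principal_dx", "code": "578.1",  "class": "LGIB", "n_correct": 40, "n_incorrect": 20},
    {"field": "principal_dx", "code": "578.9",  "class": "LGIB", "n_correct": 24, "n_incorrect": 17},
    {"field": "principal_dx", "code": "569.85", "class": "LGIB", "n_correct": 10, "n_incorrect": 2},
    {"field": "secondary_dx", "code": "562.12", "class": "LGIB", "n_correct": 9,  "n_incorrect": 4},
    {"field": "secondary_dx", "code": "211.3",  "class": "LGIB", "n_correct": 13, "n_incorrect": 41},
    {"field": "secondary_dx", "code": "578.9",  "class": "LGIB", "n_correct": 10, "n_incorrect": 29},
    {"field": "secondary_dx", "code": "455.2",  "class": "LGIB", "n_correct": 6,  "n_incorrect": 1},
    {"field": "principal_dx", "code": "556.9",  "class": "LGIB", "n_correct": 6,  "n_incorrect": 4},
    {"field": "secondary_dx", "code": "455.0",  "class": "LGIB", "n_correct": 5,  "n_incorrect": 5}
  ],
  "default_counts": {"n_correct": 6458, "n_incorrect": 41}
}
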