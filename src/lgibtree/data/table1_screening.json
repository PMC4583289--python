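{
  "provenance": "36 ICD-9-CM screening codes for potential lower gastrointestinal bleeding, with derivation-cohort per-code tallies (principal / secondary count and fraction chart-confirmed LGIB)",
  "cohort": {
    "n": 6974,
    "screened": 768,
    "lgib": 297,
    "secondary_dx_mean": 8.0,
    "secondary_dx_sd": 4.6,
    "principal_proc_n": 5068,
    "secondary_proc_mean": 1.2,
    "secondary_proc_sd": 1.9
  },
  "codes": [
    {"code": "003.0",  "description": "Salmonella gastroenteritis",                        "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 1,   "p_lgib": 0.00}},
    {"code": "006.2",  "description": "Amebic nondysenteric colitis",                      "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 0,   "p_lgib": null}},
    {"code": "153.0",  "description": "Hepatic flexure",                                   "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 1,   "p_lgib": 0.00}},
    {"code": "153.1",  "description": "Malignant neoplasm transverse colon",               "principal": {"n": 2,  "p_lgib": 0.00}, "secondary": {"n": 0,   "p_lgib": null}},
    {"code": "153.3",  "description": "Malignant neoplasm sigmoid colon",                  "principal": {"n": 2,  "p_lgib": 0.00}, "secondary": {"n": 1,   "p_lgib": 0.00}},
    {"code": "153.4",  "description": "Malignant neoplasm cecum",                          "principal": {"n": 3,  "p_lgib": 1.00}, "secondary": {"n": 0,   "p_lgib": null}},
    {"code": "153.8",  "description": "Malignant neoplasm colon, other specified site",    "principal": {"n": 1,  "p_lgib": 1.00}, "secondary": {"n": 1,   "p_lgib": 0.00}},
    {"code": "153.9",  "description": "Malignant neoplasm colon, unspecified",             "principal": {"n": 1,  "p_lgib": 1.00}, "secondary": {"n": 7,   "p_lgib": 0.14}},
    {"code": "211.3",  "description": "Benign neoplasm of colon",                          "principal": {"n": 12, "p_lgib": 0.25}, "secondary": {"n": 103, "p_lgib": 0.46}},
    {"code": "455.0",  "description": "Internal hemorrhoid without complication",          "principal": {"n": 1,  "p_lgib": 1.00}, "secondary": {"n": 38,  "p_lgib": 0.66}},
    {"code": "455.2",  "description": "Internal hemorrhoids with other complication",      "principal": {"n": 7,  "p_lgib": 1.00}, "secondary": {"n": 11,  "p_lgib": 0.82}},
    {"code": "455.5",  "description": "External hemorrhoids with other complication",      "principal": {"n": 3,  "p_lgib": 1.00}, "secondary": {"n": 8,   "p_lgib": 0.50}},
    {"code": "455.8",  "description": "Unspecified hemorrhoids with other complication",   "principal": {"n": 2,  "p_lgib": 1.00}, "secondary": {"n": 8,   "p_lgib": 0.88}},
    {"code": "456.8",  "description": "Varices of other sites",                            "principal": {"n": 1,  "p_lgib": 0.00}, "secondary": {"n": 4,   "p_lgib": 0.00}},
    {"code": "556.2",  "description": "Ulcerative proctitis",                              "principal": {"n": 1,  "p_lgib": 0.00}, "secondary": {"n": 1,   "p_lgib": 0.00}},
    {"code": "556.3",  "description": "Ulcerative proctosigmoiditis",                      "principal": {"n": 1,  "p_lgib": 1.00}, "secondary": {"n": 0,   "p_lgib": null}},
    {"code": "556.5",  "description": "Left-sided ulcerative colitis",                     "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 1,   "p_lgib": 0.00}},
    {"code": "556.6",  "description": "Universal ulcerative colitis",                      "principal": {"n": 2,  "p_lgib": 0.50}, "secondary": {"n": 4,   "p_lgib": 0.00}},
    {"code": "556.8",  "description": "Other ulcerative colitis",                          "principal": {"n": 2,  "p_lgib": 1.00}, "secondary": {"n": 3,   "p_lgib": 0.67}},
    {"code": "556.9",  "description": "Ulcerative colitis, unspecified",                   "principal": {"n": 12, "p_lgib": 0.67}, "secondary": {"n": 12,  "p_lgib": 0.25}},
    {"code": "558.1",  "description": "Radiation gastroenteritis",                         "principal": {"n": 5,  "p_lgib": 0.40}, "secondary": {"n": 10,  "p_lgib": 0.00}},
    {"code": "558.2",  "description": "Toxic gastroenteritis",                             "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 0,   "p_lgib": null}},
    {"code": "558.9",  "description": "Other noninfectious gastroenteritis",               "principal": {"n": 29, "p_lgib": 0.17}, "secondary": {"n": 62,  "p_lgib": 0.13}},
    {"code": "562.02", "description": "Diverticulosis of small intestine with hemorrhage", "principal": {"n": 2,  "p_lgib": 0.50}, "secondary": {"n": 2,   "p_lgib": 1.00}},
    {"code": "562.03", "description": "Diverticulitis of small intestine with hemorrhage", "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 0,   "p_lgib": null}},
    {"code": "562.10", "description": "Diverticulosis of colon without hemorrhage",        "principal": {"n": 4,  "p_lgib": 0.25}, "secondary": {"n": 181, "p_lgib": 0.26}},
    {"code": "562.12", "description": "Diverticulosis of colon with hemorrhage",           "principal": {"n": 73, "p_lgib": 0.97}, "secondary": {"n": 14,  "p_lgib": 0.71}},
    {"code": "562.13", "description": "Diverticulitis of colon with hemorrhage",           "principal": {"n": 8,  "p_lgib": 0.88}, "secondary": {"n": 1,   "p_lgib": 0.00}},
    {"code": "569.3",  "description": "Hemorrhage of rectum and anus",                     "principal": {"n": 3,  "p_lgib": 1.00}, "secondary": {"n": 16,  "p_lgib": 0.38}},
    {"code": "569.82", "description": "Ulceration of intestine",                           "principal": {"n": 1,  "p_lgib": 1.00}, "secondary": {"n": 5,   "p_lgib": 0.80}},
    {"code": "569.85", "description": "Angiodysplasia of intestine with hemorrhage",       "principal": {"n": 12, "p_lgib": 0.83}, "secondary": {"n": 8,   "p_lgib": 0.13}},
    {"code": "569.89", "description": "Other specified intestinal disorders",              "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 15,  "p_lgib": 0.27}},
    {"code": "569.9",  "description": "Unspecified disorder of intestine",                 "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 7,   "p_lgib": 0.29}},
    {"code": "578.1",  "description": "Blood in stool",                                   "principal": {"n": 60, "p_lgib": 0.67}, "secondary": {"n": 160, "p_lgib": 0.41}},
    {"code": "578.9",  "description": "Gastrointestinal hemorrhage, unspecified",          "principal": {"n": 41, "p_lgib": 0.59}, "secondary": {"n": 41,  "p_lgib": 0.27}},
    {"code": "751.0",  "description": "Meckel's diverticulum",                             "principal": {"n": 0,  "p_lgib": null}, "secondary": {"n": 0,   "p_lgib": null}}
  ]
}
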