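{
  "description": "Confusion-matrix counts and the published eight-metric panel from a retrospective three-hospital AECOPD cohort (n=1158, 210 imaging-confirmed PE) in which every patient was imaged under the standard algorithm and the other four strategies were reassessed from the stored Wells score and D-dimer. Null = not applicable (the standard algorithm imaged everyone, so it has no rule-outs).",
  "n_total": 1158,
  "counts": {
    "standard": {"tp": 210, "fp": 948, "fn": null, "tn": null},
    "age_adjusted": {"tp": 165, "fp": 246, "fn": 45, "tn": 702},
    "years": {"tp": 150, "fp": 222, "fn": 60, "tn": 726},
    "perc": {"tp": 207, "fp": 933, "fn": 3, "tn": 15},
    "peged": {"tp": 186, "fp": 183, "fn": 24, "tn": 765}
  },
  "published_metrics": {
    "standard": {"sensitivity": null, "specificity": null, "ppv": 18.1, "npv": null,
                 "plr": null, "nlr": null, "youden": null, "accuracy": null},
    "age_adjusted": {"sensitivity": 78.6, "specificity": 74.1, "ppv": 40.1, "npv": 94.0,
                     "plr": 3.034, "nlr": 0.289, "youden": 0.527, "accuracy": 74.9},
    "years": {"sensitivity": 71.4, "specificity": 76.6, "ppv": 40.3, "npv": 92.4,
              "plr": 3.051, "nlr": 0.373, "youden": 0.480, "accuracy": 75.6},
    "perc": {"sensitivity": 98.6, "specificity": 1.6, "ppv": 18.2, "npv": 83.3,
             "plr": 1.002, "nlr": 0.875, "youden": 0.002, "accuracy": 19.2},
    "peged": {"sensitivity": 88.6, "specificity": 80.7, "ppv": 50.4, "npv": 97.0,
              "plr": 4.591, "nlr": 0.141, "youden": 0.693, "accuracy": 82.1}
  },
  "published_imaging_counts": {"standard": 1158, "age_adjusted": 411, "years": 372,
                               "perc": 1140, "peged": 369},
  "published_missed_counts": {"age_adjusted": 45, "years": 60, "perc": 3, "peged": 24},
  "known_discrepancies": {
    "age_adjusted.plr": "published value 3.034; both rounding paths give 3.035 (0.786/0.259 = 3.0347, apparently truncated in print)"
  },
  "group_counts_2x2": {
    "n_pe_absent": 948,
    "n_pe_present": 210,
    "items": {
      "age_lt_50": [26, 5], "female": [303, 72], "smoker": [633, 145],
      "dvt_signs": [96, 66], "pe_likely": [555, 177], "hr_gt_100": [498, 108],
      "recent_immobilization": [640, 186], "recent_surgery": [99, 45],
      "history_vte": [84, 21], "hemoptysis": [66, 12], "active_cancer": [147, 54],
      "sao2_le_94": [806, 188], "oral_hormone_use": [275, 78]
    },
    "published_p": {
      "age_lt_50": 0.769, "female": 0.515, "smoker": 0.525, "dvt_signs": "<0.001",
      "pe_likely": "<0.001", "hr_gt_100": 0.772, "recent_immobilization": "<0.001",
      "recent_surgery": "<0.001", "history_vte": 0.603, "hemoptysis": 0.514,
      "active_cancer": "<0.001", "sao2_le_94": 0.090, "oral_hormone_use": 0.021
    }
  },
  "summary_stats": {
    "d_dimer": {"pe_absent": [1191, 676], "pe_present": [3118, 1635]},
    "wells_score": {"pe_absent": [3.3, 1.4], "pe_present": [6.5, 3.3]},
    "age": {"pe_absent": [66.9, 18.6], "pe_present": [68.1, 20.3]},
    "bode_index": {"pe_absent": [5.9, 3.6], "pe_present": [6.2, 3.4]}
  }
}
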