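{
  "description": "Published contingency tables of the original clinical cohort: 96 CTA examinations with CTP, evaluated against CTP hypoperfusion (cta_vs_ctp) and against endovascular vasospasm treatment within 24 h (vs_treatment, combined_vs_treatment). 'printed' holds the whole-percent metric values as published; 'rounding_anomalies' lists the single cell whose printed percent is not reproducible from the counts under half-away-from-zero rounding via one decimal.",
  "cta_vs_ctp": {
    "cta_k1": {"tp": 25, "fp": 40, "fn": 3, "tn": 28, "printed": {"sensitivity": 89, "specificity": 41, "npv": 90, "ppv": 39}},
    "cta_k2": {"tp": 20, "fp": 23, "fn": 8, "tn": 45, "printed": {"sensitivity": 71, "specificity": 66, "npv": 85, "ppv": 47}},
    "cta_k3": {"tp": 17, "fp": 9, "fn": 11, "tn": 59, "printed": {"sensitivity": 61, "specificity": 87, "npv": 84, "ppv": 65}}
  },
  "vs_treatment": {
    "ctp": {"tp": 12, "fp": 16, "fn": 7, "tn": 61, "printed": {"sensitivity": 63, "specificity": 79, "npv": 90, "ppv": 43}},
    "cta_k1": {"tp": 17, "fp": 48, "fn": 2, "tn": 29, "printed": {"sensitivity": 90, "specificity": 38, "npv": 94, "ppv": 26}},
    "cta_k2": {"tp": 16, "fp": 27, "fn": 3, "tn": 50, "printed": {"sensitivity": 84, "specificity": 65, "npv": 94, "ppv": 37}},
    "cta_k3": {"tp": 13, "fp": 13, "fn": 6, "tn": 64, "printed": {"sensitivity": 69, "specificity": 83, "npv": 91, "ppv": 50}}
  },
  "combined_vs_treatment": {
    "combined_k1": {"tp": 12, "fp": 13, "fn": 7, "tn": 64, "printed": {"sensitivity": 63, "specificity": 83, "npv": 90, "ppv": 48}},
    "combined_k2": {"tp": 12, "fp": 8, "fn": 7, "tn": 69, "printed": {"sensitivity": 63, "specificity": 90, "npv": 91, "ppv": 60}},
    "combined_k3": {"tp": 11, "fp": 6, "fn": 8, "tn": 71, "printed": {"sensitivity": 58, "specificity": 92, "npv": 90, "ppv": 65}}
  },
  "rounding_anomalies": [["vs_treatment", "cta_k3", "sensitivity"]]
}
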