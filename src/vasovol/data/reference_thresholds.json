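[
  {"segment_class": "BA", "threshold": 4.3, "ci_low": 2.8, "ci_high": 10.3, "n_examinations": 18, "n_patients": 10},
  {"segment_class": "PCA", "threshold": 1.0, "ci_low": 0.9, "ci_high": 2.7, "n_examinations": 18, "n_patients": 10},
  {"segment_class": "ICA", "threshold": 9.2, "ci_low": 5.5, "ci_high": 9.8, "n_examinations": 19, "n_patients": 10},
  {"segment_class": "M1", "threshold": 5.0, "ci_low": 4.6, "ci_high": 8.0, "n_examinations": 20, "n_patients": 10},
  {"segment_class": "M2_frontal", "threshold": 1.8, "ci_low": 1.0, "ci_high": 4.3, "n_examinations": 17, "n_patients": 9},
  {"segment_class": "M2_temporal", "threshold": 3.1, "ci_low": 2.2, "ci_high": 3.9, "n_examinations": 20, "n_patients": 10},
  {"segment_class": "A1", "threshold": 2.7, "ci_low": 1.6, "ci_high": 3.7, "n_examinations": 19, "n_patients": 10},
  {"segment_class": "A2", "threshold": 2.1, "ci_low": 1.6, "ci_high": 4.0, "n_examinations": 17, "n_patients": 10}
]
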