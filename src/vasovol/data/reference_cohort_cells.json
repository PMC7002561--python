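[
  {"n_severe": 3, "ctp": true,  "treated": true,  "count": 11},
  {"n_severe": 3, "ctp": true,  "treated": false, "count": 6},
  {"n_severe": 3, "ctp": false, "treated": true,  "count": 2},
  {"n_severe": 3, "ctp": false, "treated": false, "count": 7},
  {"n_severe": 2, "ctp": true,  "treated": true,  "count": 1},
  {"n_severe": 2, "ctp": true,  "treated": false, "count": 2},
  {"n_severe": 2, "ctp": false, "treated": true,  "count": 2},
  {"n_severe": 2, "ctp": false, "treated": false, "count": 12},
  {"n_severe": 1, "ctp": true,  "treated": true,  "count": 0},
  {"n_severe": 1, "ctp": true,  "treated": false, "count": 5},
  {"n_severe": 1, "ctp": false, "treated": true,  "count": 1},
  {"n_severe": 1, "ctp": false, "treated": false, "count": 16},
  {"n_severe": 0, "ctp": true,  "treated": true,  "count": 0},
  {"n_severe": 0, "ctp": true,  "treated": false, "count": 3},
  {"n_severe": 0, "ctp": false, "treated": true,  "count": 2},
  {"n_severe": 0, "ctp": false, "treated": false, "count": 26}
]
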