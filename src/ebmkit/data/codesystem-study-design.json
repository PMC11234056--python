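{
  "system": "urn:ebmkit:codesystem:study-design",
  "title": "Study Design (representative stub)",
  "concept": [
    {"code": "interventional", "display": "interventional study"},
    {"code": "randomized-trial", "display": "randomized controlled trial", "parent": "interventional"},
    {"code": "parallel-group", "display": "parallel-group design", "parent": "randomized-trial"},
    {"code": "crossover", "display": "crossover design", "parent": "randomized-trial"},
    {"code": "observational", "display": "observational study"},
    {"code": "cohort", "display": "cohort study", "parent": "observational"},
    {"code": "case-control", "display": "case-control study", "parent": "observational"},
    {"code": "cross-sectional", "display": "cross-sectional study", "parent": "observational"}
  ]
}
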