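{
  "system": "urn:ebmkit:codesystem:statistical-model",
  "title": "Statistical Model",
  "concept": [
    {"code": "fixed-effect", "display": "fixed-effect inverse-variance"},
    {"code": "random-effects", "display": "random-effects (DerSimonian-Laird)"},
    {"code": "between-study-variance", "display": "between-study variance"},
    {"code": "covariate-adjusted", "display": "covariate-adjusted"},
    {"code": "bayesian", "display": "Bayesian model"}
  ]
}
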