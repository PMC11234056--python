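{
  "system": "urn:ebmkit:codesystem:attribute-estimate-type",
  "title": "Attribute Estimate Type",
  "concept": [
    {"code": "confidence-interval", "display": "confidence interval"},
    {"code": "credible-interval", "display": "credible interval"},
    {"code": "p-value", "display": "P value"},
    {"code": "standard-error", "display": "standard error"},
    {"code": "cochran-q", "display": "Cochran's Q"},
    {"code": "i-squared", "display": "I-squared"},
    {"code": "tau-squared", "display": "tau-squared"}
  ]
}
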