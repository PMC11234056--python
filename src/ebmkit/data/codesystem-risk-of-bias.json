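{
  "system": "urn:ebmkit:codesystem:risk-of-bias",
  "title": "Risk of Bias (representative stub)",
  "concept": [
    {"code": "bias", "display": "bias"},
    {"code": "selection-bias", "display": "selection bias", "parent": "bias"},
    {"code": "performance-bias", "display": "performance bias", "parent": "bias"},
    {"code": "detection-bias", "display": "detection bias", "parent": "bias"},
    {"code": "attrition-bias", "display": "attrition bias", "parent": "bias"},
    {"code": "reporting-bias", "display": "reporting bias", "parent": "bias"},
    {"code": "confounding-bias", "display": "confounding bias", "parent": "bias"}
  ]
}
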