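{
  "system": "urn:ebmkit:codesystem:certainty-aspect",
  "title": "Certainty Aspect",
  "concept": [
    {"code": "overall-certainty", "display": "overall certainty", "definition": "Overall confidence in the evidence."},
    {"code": "risk-of-bias", "display": "risk of bias"},
    {"code": "inconsistency", "display": "inconsistency"},
    {"code": "indirectness", "display": "indirectness"},
    {"code": "imprecision", "display": "imprecision"},
    {"code": "publication-bias", "display": "publication bias"},
    {"code": "dose-response-gradient", "display": "dose-response gradient"},
    {"code": "plausible-confounding", "display": "plausible confounding"},
    {"code": "large-effect-size", "display": "large effect size"}
  ]
}
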