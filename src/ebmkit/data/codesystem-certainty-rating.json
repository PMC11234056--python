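{
  "system": "urn:ebmkit:codesystem:certainty-rating",
  "title": "Certainty Rating",
  "concept": [
    {"code": "high", "display": "High"},
    {"code": "moderate", "display": "Moderate"},
    {"code": "low", "display": "Low"},
    {"code": "very-low", "display": "Very low"}
  ]
}
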