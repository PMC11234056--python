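{
  "system": "urn:ebmkit:codesystem:certainty-modifier",
  "title": "Certainty Rating Modifier",
  "concept": [
    {"code": "no-concern", "display": "no concern"},
    {"code": "serious-concern", "display": "serious concern"},
    {"code": "very-serious-concern", "display": "very serious concern"},
    {"code": "present", "display": "present"},
    {"code": "absent", "display": "absent"}
  ]
}
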