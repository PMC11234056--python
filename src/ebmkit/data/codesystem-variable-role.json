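{
  "system": "urn:ebmkit:codesystem:variable-role",
  "title": "Evidence Variable Role",
  "concept": [
    {"code": "population", "display": "population"},
    {"code": "subpopulation", "display": "subpopulation"},
    {"code": "exposure", "display": "exposure"},
    {"code": "reference-exposure", "display": "reference exposure"},
    {"code": "measured-variable", "display": "measured variable"},
    {"code": "confounder", "display": "confounder"}
  ]
}
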