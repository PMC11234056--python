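{
  "valueSets": [
    {"id": "statistic-type", "include": [{"system": "urn:ebmkit:codesystem:statistic-type", "mode": "all"}]},
    {"id": "certainty-aspect", "include": [{"system": "urn:ebmkit:codesystem:certainty-aspect", "mode": "all"}]},
    {
      "id": "certainty-rating",
      "include": [
        {"system": "urn:ebmkit:codesystem:certainty-rating", "mode": "all"},
        {"system": "urn:ebmkit:codesystem:certainty-modifier", "mode": "all"}
      ]
    },
    {"id": "variable-role", "include": [{"system": "urn:ebmkit:codesystem:variable-role", "mode": "all"}]},
    {"id": "attribute-estimate-type", "include": [{"system": "urn:ebmkit:codesystem:attribute-estimate-type", "mode": "all"}]},
    {"id": "statistical-model", "include": [{"system": "urn:ebmkit:codesystem:statistical-model", "mode": "all"}]},
    {"id": "study-design", "include": [{"system": "urn:ebmkit:codesystem:study-design", "mode": "all"}]},
    {"id": "risk-of-bias", "include": [{"system": "urn:ebmkit:codesystem:risk-of-bias", "mode": "all"}]}
  ]
}
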