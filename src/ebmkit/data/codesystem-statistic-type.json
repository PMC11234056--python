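{
  "system": "urn:ebmkit:codesystem:statistic-type",
  "title": "Statistic Type",
  "concept": [
    {"code": "count", "display": "count", "definition": "Number of observations or events."},
    {"code": "proportion", "display": "proportion", "definition": "Events divided by observations, in [0, 1]."},
    {"code": "mean", "display": "mean", "definition": "Arithmetic mean."},
    {"code": "median", "display": "median", "definition": "50th percentile."},
    {"code": "standard-deviation", "display": "standard deviation"},
    {"code": "variance", "display": "variance"},
    {"code": "interquartile-range", "display": "interquartile range"},
    {"code": "range", "display": "range"},
    {"code": "mean-difference", "display": "mean difference"},
    {"code": "median-difference", "display": "median difference"},
    {"code": "standardized-mean-difference", "display": "standardized mean difference"},
    {"code": "odds-ratio", "display": "odds ratio", "definition": "Odds of the event in the exposed arm divided by odds in the reference arm."},
    {"code": "relative-risk", "display": "relative risk", "definition": "Risk in the exposed arm divided by risk in the reference arm."},
    {"code": "risk-difference", "display": "risk difference"},
    {"code": "hazard-ratio", "display": "hazard ratio"},
    {"code": "incidence-rate", "display": "incidence rate"},
    {"code": "incidence-rate-ratio", "display": "incidence rate ratio"},
    {"code": "incidence-rate-difference", "display": "incidence rate difference"},
    {"code": "regression-coefficient", "display": "regression coefficient"},
    {"code": "correlation-coefficient", "display": "correlation coefficient"},
    {"code": "c-statistic", "display": "C-statistic"},
    {"code": "number-needed-to-treat", "display": "number needed to treat"}
  ]
}
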