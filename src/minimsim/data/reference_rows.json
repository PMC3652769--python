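[
  {"source_table": "small-trial imbalance cutoffs", "row": "N=10", "quantity": "cutoff_percent", "value": 40.0, "tolerance": 0.0},
  {"source_table": "small-trial imbalance cutoffs", "row": "N=20", "quantity": "cutoff_percent", "value": 20.0, "tolerance": 0.0},
  {"source_table": "small-trial imbalance cutoffs", "row": "N=30", "quantity": "cutoff_percent", "value": 10.0, "tolerance": 0.0},
  {"source_table": "small-trial imbalance cutoffs", "row": "N=40", "quantity": "cutoff_percent", "value": 10.0, "tolerance": 0.0},
  {"source_table": "small-trial imbalance cutoffs", "row": "N>=50", "quantity": "cutoff_percent", "value": 5.0, "tolerance": 0.0},

  {"source_table": "two-treatment case", "row": "one binary variable, equal prevalence, P=1.0", "quantity": "tie_pct", "value": 50.0, "tolerance": 3.0},
  {"source_table": "two-treatment case", "row": "one binary variable, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 50.0, "tolerance": 3.0},
  {"source_table": "two-treatment case", "row": "two binary variables, equal prevalence, P=1.0", "quantity": "tie_pct", "value": 28.0, "tolerance": 3.0},
  {"source_table": "two-treatment case", "row": "two binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 72.0, "tolerance": 3.0},
  {"source_table": "two-treatment case", "row": "three binary variables, equal prevalence, P=1.0", "quantity": "tie_pct", "value": 20.0, "tolerance": 3.0},
  {"source_table": "two-treatment case", "row": "three binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 80.0, "tolerance": 3.0},
  {"source_table": "two-treatment case", "row": "four binary variables, equal prevalence, P=1.0", "quantity": "tie_pct", "value": 15.0, "tolerance": 3.0},
  {"source_table": "two-treatment case", "row": "four binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 85.0, "tolerance": 3.0},

  {"source_table": "three-treatment case", "row": "one binary variable, equal prevalence, P=1.0", "quantity": "tie_pct", "value": 67.0, "tolerance": 3.0},
  {"source_table": "three-treatment case", "row": "one binary variable, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 33.0, "tolerance": 3.0},
  {"source_table": "three-treatment case", "row": "two binary variables, equal prevalence, P=1.0", "quantity": "tie_pct", "value": 44.0, "tolerance": 3.0},
  {"source_table": "three-treatment case", "row": "two binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 56.0, "tolerance": 3.0},
  {"source_table": "three-treatment case", "row": "three binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 67.0, "tolerance": 3.0},
  {"source_table": "three-treatment case", "row": "four binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 74.0, "tolerance": 3.0},

  {"source_table": "four-treatment case", "row": "one binary variable, equal prevalence, P=1.0", "quantity": "tie_pct", "value": 76.0, "tolerance": 3.0},
  {"source_table": "four-treatment case", "row": "one binary variable, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 24.0, "tolerance": 3.0},
  {"source_table": "four-treatment case", "row": "two binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 45.0, "tolerance": 3.0},
  {"source_table": "four-treatment case", "row": "three binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 58.0, "tolerance": 3.0},
  {"source_table": "four-treatment case", "row": "four binary variables, equal prevalence, P=1.0", "quantity": "deterministic_pct", "value": 67.0, "tolerance": 3.0},

  {"source_table": "two-treatment summary", "row": "three binary variables, equal prevalence, N=200 to 300", "quantity": "recommended_p", "value": 0.7, "tolerance": 0.0},
  {"source_table": "two-treatment summary", "row": "three binary variables, equal prevalence, N=200 to 300", "quantity": "predictability_reduction_pct", "value": 17.0, "tolerance": 3.0},

  {"source_table": "maximum decrease in predictability", "row": "two treatments, one variable", "quantity": "max_decrease_pct", "value": 0.0, "value_high": 1.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "two treatments, two variables", "quantity": "max_decrease_pct", "value": 4.0, "value_high": 12.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "two treatments, three variables", "quantity": "max_decrease_pct", "value": 6.0, "value_high": 17.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "two treatments, four variables", "quantity": "max_decrease_pct", "value": 7.0, "value_high": 20.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "three treatments, one variable", "quantity": "max_decrease_pct", "value": 0.0, "value_high": 1.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "three treatments, two variables", "quantity": "max_decrease_pct", "value": 2.0, "value_high": 8.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "three treatments, three variables", "quantity": "max_decrease_pct", "value": 11.0, "value_high": 12.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "three treatments, four variables", "quantity": "max_decrease_pct", "value": 10.0, "value_high": 17.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "four treatments, one variable", "quantity": "max_decrease_pct", "value": 0.0, "value_high": 1.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "four treatments, two variables", "quantity": "max_decrease_pct", "value": 0.0, "value_high": 4.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "four treatments, three variables", "quantity": "max_decrease_pct", "value": 0.0, "value_high": 9.0, "tolerance": 3.0},
  {"source_table": "maximum decrease in predictability", "row": "four treatments, four variables", "quantity": "max_decrease_pct", "value": 8.0, "value_high": 14.0, "tolerance": 3.0}
]
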