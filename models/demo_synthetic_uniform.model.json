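{
 "format": "lncclass-model",
 "version": 1,
 "feature_names": [
  "exon_hexamer_score",
  "exon_hexamer_distance",
  "exon_gc",
  "mcss_length",
  "mcss_score",
  "mcss_score_percentage",
  "orf_length",
  "orf_coverage",
  "orf_fickett",
  "orf_hexamer_score",
  "orf_hexamer_distance"
 ],
 "weights": [
  0.052265083178904076,
  -0.5568237982637525,
  -0.7373095591723724,
  0.012343127360647488,
  0.008389294220731324,
  -2.082479986983272,
  -0.017922578374540022,
  20.287845201553488,
  -3.3083921553643227,
  1.8835992991982404,
  0.4719904330569576
 ],
 "intercept": -0.2756840063934545,
 "C": 1291.5496650148827,
 "cutoff": 0.5,
 "hexamer_table_digest": "4ae255869b30e0d2",
 "scaler_mean": null,
 "scaler_scale": null,
 "provenance": {
  "n_samples": 1000,
  "n_coding": 500,
  "n_noncoding": 500,
  "cv_folds": 10,
  "cv_seed": 0,
  "C_grid": [
   0.0001,
   0.000774263682681127,
   0.005994842503189409,
   0.046415888336127774,
   0.3593813663804626,
   2.782559402207126,
   21.54434690031882,
   166.81005372000558,
   1291.5496650148827,
   10000.0
  ],
  "cv_accuracy": 0.9639999999999999,
  "standardize": false,
  "distance_definition": "sum_i(S_m - S_i)/2",
  "orf_convention": "ATG start; terminal stop optional at sequence end",
  "log_base": "e",
  "training_data": "synthetic (uniform noncoding background, generator seed 42)"
 }
}
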