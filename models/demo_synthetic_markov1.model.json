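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
  0.8930920609674967,
  -0.14586328659642295,
  0.08158350230623486,
  0.009483853783801153,
  -0.02369075606747059,
  -0.0002869515060234356,
  -0.0049849217152155454,
  12.948279903612638,
  -0.6327032942194887,
  6.5974534507488,
  -0.7773680364010888
 ],
 "intercept": -2.9262630177724187,
 "C": 21.54434690031882,
 "cutoff": 0.5,
 "hexamer_table_digest": "68f9c49f3c1d0c4e",
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
  "cv_accuracy": 0.968,
  "standardize": false,
  "distance_definition": "sum_i(S_m - S_i)/2",
  "orf_convention": "ATG start; terminal stop optional at sequence end",
  "log_base": "e",
  "training_data": "synthetic (markov1 noncoding background, generator seed 42)"
 }
}
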