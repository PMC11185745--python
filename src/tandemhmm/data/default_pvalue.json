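{
 "ploc": 2.5825399834866403,
 "pscale": 0.989600027916596,
 "pfreq": 0.0019543,
 "_provenance": {
  "method": "stats.calibrate",
  "null_length": 10000000,
  "model": "package defaults (k=100)",
  "seed": 20240601
 }
}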