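{
 "brand_label": "MED-EL (representative 12-channel, 70-8500 Hz)",
 "n_electrodes": 12,
 "freq_step_hz": 1,
 "min_band_width_hz": 1,
 "default_bands": [
  [
   70.0,
   104.0
  ],
  [
   104.0,
   156.0
  ],
  [
   156.0,
   232.0
  ],
  [
   232.0,
   347.0
  ],
  [
   347.0,
   517.0
  ],
  [
   517.0,
   771.0
  ],
  [
   771.0,
   1151.0
  ],
  [
   1151.0,
   1717.0
  ],
  [
   1717.0,
   2561.0
  ],
  [
   2561.0,
   3820.0
  ],
  [
   3820.0,
   5698.0
  ],
  [
   5698.0,
   8500.0
  ]
 ],
 "deactivated": [],
 "indexing": "apex_first",
 "global_f_min": 70.0
}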