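{
 "brand_label": "Advanced Bionics (representative 16-channel, 248-8680 Hz)",
 "n_electrodes": 16,
 "freq_step_hz": 62,
 "min_band_width_hz": 62,
 "default_bands": [
  [
   248.0,
   310.0
  ],
  [
   310.0,
   372.0
  ],
  [
   372.0,
   496.0
  ],
  [
   496.0,
   620.0
  ],
  [
   620.0,
   744.0
  ],
  [
   744.0,
   930.0
  ],
  [
   930.0,
   1178.0
  ],
  [
   1178.0,
   1488.0
  ],
  [
   1488.0,
   1860.0
  ],
  [
   1860.0,
   2294.0
  ],
  [
   2294.0,
   2852.0
  ],
  [
   2852.0,
   3596.0
  ],
  [
   3596.0,
   4464.0
  ],
  [
   4464.0,
   5580.0
  ],
  [
   5580.0,
   6944.0
  ],
  [
   6944.0,
   8680.0
  ]
 ],
 "deactivated": [],
 "indexing": "apex_first",
 "global_f_min": 248.0
}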