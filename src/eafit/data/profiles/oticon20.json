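{
 "brand_label": "Oticon Medical (representative 20-channel, 195-8055 Hz)",
 "n_electrodes": 20,
 "freq_step_hz": 131,
 "min_band_width_hz": 131,
 "default_bands": [
  [
   195.0,
   326.0
  ],
  [
   326.0,
   457.0
  ],
  [
   457.0,
   588.0
  ],
  [
   588.0,
   719.0
  ],
  [
   719.0,
   850.0
  ],
  [
   850.0,
   981.0
  ],
  [
   981.0,
   1112.0
  ],
  [
   1112.0,
   1243.0
  ],
  [
   1243.0,
   1374.0
  ],
  [
   1374.0,
   1505.0
  ],
  [
   1505.0,
   1636.0
  ],
  [
   1636.0,
   1767.0
  ],
  [
   1767.0,
   2160.0
  ],
  [
   2160.0,
   2684.0
  ],
  [
   2684.0,
   3208.0
  ],
  [
   3208.0,
   3863.0
  ],
  [
   3863.0,
   4649.0
  ],
  [
   4649.0,
   5566.0
  ],
  [
   5566.0,
   6745.0
  ],
  [
   6745.0,
   8055.0
  ]
 ],
 "deactivated": [],
 "indexing": "apex_first",
 "global_f_min": 195.0
}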