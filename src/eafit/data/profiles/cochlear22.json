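{
 "brand_label": "Cochlear (representative 22-channel, 188-7938 Hz)",
 "n_electrodes": 22,
 "freq_step_hz": 1,
 "min_band_width_hz": 62,
 "default_bands": [
  [
   188,
   313
  ],
  [
   313,
   438
  ],
  [
   438,
   563
  ],
  [
   563,
   688
  ],
  [
   688,
   813
  ],
  [
   813,
   938
  ],
  [
   938,
   1063
  ],
  [
   1063,
   1188
  ],
  [
   1188,
   1313
  ],
  [
   1313,
   1563
  ],
  [
   1563,
   1813
  ],
  [
   1813,
   2063
  ],
  [
   2063,
   2313
  ],
  [
   2313,
   2688
  ],
  [
   2688,
   3063
  ],
  [
   3063,
   3563
  ],
  [
   3563,
   4063
  ],
  [
   4063,
   4688
  ],
  [
   4688,
   5313
  ],
  [
   5313,
   6063
  ],
  [
   6063,
   6938
  ],
  [
   6938,
   7938
  ]
 ],
 "deactivated": [],
 "indexing": "apex_first",
 "global_f_min": 188
}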