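{
 "geometry": {
  "distance": 100.0,
  "wavelength": 1.0,
  "beam_center": [
   12.8,
   12.8
  ],
  "pixel_size": 0.1,
  "image_size": [
   256,
   256
  ]
 },
 "background_mean": 10.0,
 "spots": [
  [
   [
    64.0,
    64.0
   ],
   600.0,
   1.5
  ],
  [
   [
    128.0,
    170.0
   ],
   600.0,
   1.5
  ],
  [
   [
    200.0,
    90.0
   ],
   600.0,
   1.5
  ]
 ],
 "rings": [],
 "masked_regions": [],
 "saturation": 65535,
 "seed": 0
}
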