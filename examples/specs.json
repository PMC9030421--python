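{
  "classes": [
    {
      "name": "plum_like",
      "size_px": [170.0, 14.0],
      "aspect": [0.66, 0.045],
      "squareness": [2.6, 0.25],
      "boundary_noise": 0.02,
      "n": 30
    },
    {
      "name": "watermelon_like",
      "size_px": [100.0, 8.0],
      "aspect": [0.6, 0.04],
      "squareness": [2.1, 0.2],
      "boundary_noise": 0.015,
      "n": 30
    },
    {
      "name": "grape_like",
      "size_px": [47.0, 4.0],
      "aspect": [0.56, 0.05],
      "squareness": [1.8, 0.2],
      "boundary_noise": 0.03,
      "n": 30
    }
  ],
  "unknown": {
    "from_class": "watermelon_like",
    "n": 20
  }
}
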