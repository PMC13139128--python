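{
  "source": "published CARS-SPA selection for the NSS-stage apple-leaf dataset",
  "grid_start_nm": 400,
  "rmse": 0.1540,
  "wavelengths_nm": [411, 450, 522, 539, 917, 975, 1359, 1425, 2045, 2181, 2215, 2324, 2382, 2387, 2394]
}
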