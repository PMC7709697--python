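{
  "animal_id": "animal2",
  "d_r": 9.8,
  "delta_d": 5.0,
  "h_r": 4.2,
  "delta_h": 1.0,
  "h_j": 2.0,
  "rho_j": 1.024,
  "rho_w": 1.024,
  "C_d": 0.42,
  "g_net": 0.0,
  "t_c": 0.87,
  "t_r": 0.90,
  "freqs": [0.40, 0.50, 0.53, 0.75]
}
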