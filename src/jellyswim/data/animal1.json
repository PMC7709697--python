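{
  "animal_id": "animal1",
  "d_r": 11.3,
  "delta_d": 6.0,
  "h_r": 4.4,
  "delta_h": 1.0,
  "h_j": 2.0,
  "rho_j": 1.024,
  "rho_w": 1.024,
  "C_d": 0.42,
  "g_net": 0.0,
  "t_c": 0.70,
  "t_r": 0.73,
  "freqs": [0.09, 0.20, 0.47, 0.53, 0.81]
}
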