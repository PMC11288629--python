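{
  "comment": "Musculotendon-length polynomial coefficients: l(q) = a0 + a1s*q_shoulder + a1e*q_elbow + a2e*q_elbow^2 (metres, radians). Moment arms are the exact partial derivatives. The biarticular-flexor a1s is -0.03 m/rad (a -0.3 value sometimes quoted would drive fiber length negative inside the joint-limit box).",
  "muscles": [
    {"name": "shoulder_flexor",      "a0": 0.151,  "a1e": 0.0,    "a1s": -0.03, "a2e": 0.0},
    {"name": "shoulder_extensor",    "a0": 0.2322, "a1e": 0.0,    "a1s": 0.03,  "a2e": 0.0},
    {"name": "elbow_flexor",         "a0": 0.2859, "a1e": -0.014, "a1s": 0.0,   "a2e": -0.004},
    {"name": "elbow_extensor",       "a0": 0.2355, "a1e": 0.025,  "a1s": 0.0,   "a2e": -0.0022},
    {"name": "biarticular_flexor",   "a0": 0.3329, "a1e": -0.016, "a1s": -0.03, "a2e": -0.0057},
    {"name": "biarticular_extensor", "a0": 0.2989, "a1e": 0.03,   "a1s": 0.03,  "a2e": -0.0032}
  ]
}
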