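{
  "comment": "Hill-type actuator constants for the six-muscle planar arm. The elbow-flexor tendon length is 0.172 m (the 0.0172 m sometimes quoted makes the rigid-tendon fiber ~2.9x optimal length everywhere, which is unphysical).",
  "normalized_slack_length": 1.4,
  "muscles": [
    {"name": "shoulder_flexor",      "max_isometric_force": 838.0,  "tendon_length": 0.039, "optimal_muscle_length": 0.134},
    {"name": "shoulder_extensor",    "max_isometric_force": 1207.0, "tendon_length": 0.066, "optimal_muscle_length": 0.140},
    {"name": "elbow_flexor",         "max_isometric_force": 1422.0, "tendon_length": 0.172, "optimal_muscle_length": 0.092},
    {"name": "elbow_extensor",       "max_isometric_force": 1549.0, "tendon_length": 0.187, "optimal_muscle_length": 0.093},
    {"name": "biarticular_flexor",   "max_isometric_force": 414.0,  "tendon_length": 0.204, "optimal_muscle_length": 0.137},
    {"name": "biarticular_extensor", "max_isometric_force": 603.0,  "tendon_length": 0.217, "optimal_muscle_length": 0.127}
  ]
}
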