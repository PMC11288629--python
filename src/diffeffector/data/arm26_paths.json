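{
  "comment": "Muscle fixation points for the six-muscle arm with geometric (non-approximated) moment arms. body 0 = world (coordinates are world x,y); body 1 = upper arm; body 2 = forearm (first coordinate along the bone from its origin, second orthogonal). Shoulder sits at the world origin.",
  "muscles": [
    {"name": "shoulder_flexor",      "points": [[0, -0.15, 0.03], [1, 0.094, 0.017]]},
    {"name": "shoulder_extensor",    "points": [[0, -0.013, -0.07], [0, 0.05, 0.0], [1, 0.153, 0.0]]},
    {"name": "elbow_flexor",         "points": [[1, 0.23, 0.001], [2, 0.231, 0.01]]},
    {"name": "elbow_extensor",       "points": [[1, 0.03, 0.0], [1, 0.138, -0.019], [2, -0.04, -0.017]]},
    {"name": "biarticular_flexor",   "points": [[0, -0.052, 0.033], [2, 0.044, 0.001]]},
    {"name": "biarticular_extensor", "points": [[0, 0.02, -0.028], [2, -0.04, -0.017]]}
  ]
}
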