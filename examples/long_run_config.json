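{
  "comment": "Full-fidelity single-condition run (multi-hour): 300000 particles, 1% step. Use with: bloodwalk simulate --config long_run_config.json --out walk.h5",
  "hct": 0.43,
  "mcv_fl": 87.7,
  "n_particles": 300000,
  "TE_ms": 120.0,
  "step_fraction": 0.01,
  "seed": 1,
  "profiles": [
    {"kind": "MP", "T_ms": 40.0},
    {"kind": "MP", "T_ms": 100.0},
    {"kind": "FC", "T_ms": 70.0},
    {"kind": "FC", "T_ms": 100.0}
  ]
}
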