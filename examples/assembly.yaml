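# Scaled-down one-shell assembly in the one-step regime
scenario: assembly
eps_ss: 3.5
eps_sc: 6.0
eps_rr: 1.7
eps_gg: 1.7
eps_rg: 1.7
n_pentamers: 12
n_hexamers: 20
n_cargo_r: 107
n_cargo_g: 107
box: 25.2
n_steps: 250000
snapshot_stride: 25000
seed: 1
n_trials: 2
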