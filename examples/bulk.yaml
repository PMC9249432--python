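# Bulk cargo phase behavior at the working concentration (scaled down)
scenario: bulk
eps_rr: 1.6
eps_gg: 1.6
eps_rg: 1.0
n_cargo_r: 1000
n_cargo_g: 1000
box: 53.0
n_steps: 200000
snapshot_stride: 20000
seed: 1
n_trials: 1
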