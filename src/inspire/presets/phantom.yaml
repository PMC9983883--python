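# Desk-scale 3-level schedule for 128x128 vessel phantoms with known
# warps of up to ~10 px.  Tuned once on held-out phantom seeds.
levels:
- {subsampling_factor: 2, sigma: 2.0, control_points: 8, iterations: 500, sampling_fraction: 0.08, d_max_fraction: 0.3, step_size: 2.0, momentum: 0.9, gw_m: 0.5, gw_sigma: 1.0}
- {subsampling_factor: 2, sigma: 0.5, control_points: 16, iterations: 300, sampling_fraction: 0.05, d_max_fraction: 0.15, step_size: 1.0, momentum: 0.5, gw_m: 0.5, gw_sigma: 1.5}
- {subsampling_factor: 1, sigma: 0.0, control_points: 24, iterations: 250, sampling_fraction: 0.05, d_max_fraction: 0.1, step_size: 0.4, momentum: 0.3, gw_m: 0.5, gw_sigma: 2.0}
lam: 0.005
n_alpha: 7
q: 0.0
histeq: false
histeq_bins: 256
beta: 1.2
d_t: 10.0
t_gm: 0.0
gradient_mode: midpoint
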