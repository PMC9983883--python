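# Schedule for synthetically deformed high-resolution fundus images
# (thin vessel networks, large initial displacements).
levels:
- {subsampling_factor: 4, sigma: 5, control_points: 10, iterations: 3000, sampling_fraction: 0.004, d_max_fraction: 0.2, step_size: 20, momentum: 0.9, gw_m: 0.5, gw_sigma: 1}
- {subsampling_factor: 2, sigma: 3, control_points: 24, iterations: 2000, sampling_fraction: 0.004, d_max_fraction: 0.2, step_size: 12, momentum: 0.25, gw_m: 0.5, gw_sigma: 2}
- {subsampling_factor: 2, sigma: 1, control_points: 48, iterations: 1000, sampling_fraction: 0.004, d_max_fraction: 0.1, step_size: 8, momentum: 0.25, gw_m: 0.5, gw_sigma: 3}
- {subsampling_factor: 1, sigma: 0, control_points: 64, iterations: 250, sampling_fraction: 0.004, d_max_fraction: 0.1, step_size: 3, momentum: 0.25, gw_m: 0.5, gw_sigma: 5}
- {subsampling_factor: 1, sigma: 0, control_points: 80, iterations: 250, sampling_fraction: 0.004, d_max_fraction: 0.1, step_size: 3, momentum: 0.25, gw_m: 0.5, gw_sigma: 5}
- {subsampling_factor: 1, sigma: 0, control_points: 128, iterations: 250, sampling_fraction: 0.004, d_max_fraction: 0.1, step_size: 3, momentum: 0.25, gw_m: 0.5, gw_sigma: 5}
lam: 0.005
n_alpha: 7
q: 0.025
histeq: false
histeq_bins: 256
beta: 1.2
d_t: 20.0
t_gm: 0.0
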