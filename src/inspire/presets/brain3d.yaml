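# Schedule for subject-to-subject 3-D MR brain registration (affinely
# pre-aligned volumes; no downsampling, histogram equalization enabled).
levels:
- {subsampling_factor: 1, sigma: 4, control_points: 9, iterations: 1000, sampling_fraction: 0.005, d_max_fraction: 0.2, step_size: 3, momentum: 0.9, gw_m: 0.5, gw_sigma: 2}
- {subsampling_factor: 1, sigma: 4, control_points: 14, iterations: 1000, sampling_fraction: 0.005, d_max_fraction: 0.2, step_size: 3, momentum: 0.9, gw_m: 0.5, gw_sigma: 2}
- {subsampling_factor: 1, sigma: 4, control_points: 24, iterations: 1000, sampling_fraction: 0.005, d_max_fraction: 0.1, step_size: 2, momentum: 0.3, gw_m: 0.5, gw_sigma: 2}
- {subsampling_factor: 1, sigma: 4, control_points: 48, iterations: 750, sampling_fraction: 0.01, d_max_fraction: 0.05, step_size: 1, momentum: 0.3, gw_m: 0.5, gw_sigma: 2}
- {subsampling_factor: 1, sigma: 4, control_points: 64, iterations: 300, sampling_fraction: 0.02, d_max_fraction: 0.025, step_size: 1, momentum: 0.3, gw_m: 0.5, gw_sigma: 2}
- {subsampling_factor: 1, sigma: 4, control_points: 80, iterations: 100, sampling_fraction: 0.02, d_max_fraction: 0.025, step_size: 1, momentum: 0.3, gw_m: 0.5, gw_sigma: 2}
lam: 0.01
n_alpha: 7
q: 0.1
histeq: true
histeq_bins: 256
beta: 1.2
d_t: 20.0
t_gm: 0.0
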