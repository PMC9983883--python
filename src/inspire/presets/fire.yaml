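# Schedule for separately acquired fundus image pairs (after rigid
# pre-alignment); modest residual deformations, many alpha samples.
levels:
- {subsampling_factor: 4, sigma: 0, control_points: 12, iterations: 500, sampling_fraction: 0.05, d_max_fraction: 0.05, step_size: 5, momentum: 0.3, gw_m: 0.5, gw_sigma: 1}
- {subsampling_factor: 4, sigma: 0, control_points: 18, iterations: 500, sampling_fraction: 0.05, d_max_fraction: 0.05, step_size: 5, momentum: 0.3, gw_m: 0.5, gw_sigma: 2}
- {subsampling_factor: 4, sigma: 0, control_points: 24, iterations: 500, sampling_fraction: 0.03, d_max_fraction: 0.03, step_size: 5, momentum: 0.3, gw_m: 0.5, gw_sigma: 3}
- {subsampling_factor: 2, sigma: 0, control_points: 28, iterations: 500, sampling_fraction: 0.02, d_max_fraction: 0.02, step_size: 3, momentum: 0.3, gw_m: 0.5, gw_sigma: 5}
- {subsampling_factor: 1, sigma: 0, control_points: 32, iterations: 50, sampling_fraction: 0.02, d_max_fraction: 0.01, step_size: 2, momentum: 0.3, gw_m: 0.5, gw_sigma: 5}
- {subsampling_factor: 1, sigma: 0, control_points: 40, iterations: 50, sampling_fraction: 0.02, d_max_fraction: 0.01, step_size: 1, momentum: 0.3, gw_m: 0.5, gw_sigma: 5}
lam: 0.01
n_alpha: 31
q: 0.1
histeq: false
histeq_bins: 256
beta: 1.2
d_t: 20.0
t_gm: 0.0
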