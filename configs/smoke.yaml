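task: signal_in_noise
levels:
- 0.0
- 20.0
- 40.0
- 60.0
- 100.0
n_runs: 2
reps: 11
n_voxels_keep: 15
delay_volumes: 3
response_width: 2
grouping:
- 4
- 4
- 3
n_perm: 5
alpha: 0.005
seed: 0
tr: 1.5
trial_duration: 3.0
lead_fixation: 9.0
tail_fixation: 9.0
cycles_cutoff: 3
axis: linear
observer:
  mu: 0.0
  sigma: 62.26998
  guess: 0.0
  lapse: 0.0
rois:
- name: coupled
  coupling: psychometric
  n_voxels: 15
  amplitude_max: 0.8
  activation: 1.0
  noise_sd: 1.0
  drift_slope: 0.0
  drift_sine_amp: 0.0
  selectivity_dist: uniform
- name: 'null'
  coupling: zero
  n_voxels: 15
  amplitude_max: 0.0
  activation: 1.0
  noise_sd: 1.0
  drift_slope: 0.0
  drift_sine_amp: 0.0
  selectivity_dist: uniform
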