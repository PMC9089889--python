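# Toy-scale end-to-end run: two-state channel, 64-sample windows,
# 200 training epochs. Completes in a few minutes on one CPU core.
out_dir: scratch/demo_run
model:
  type: two_state
  k_co: 50.0          # opening rate, 1/s
  k_oc: 100.0         # closing rate, 1/s  (mean open time 10 ms)
  unitary_current: -5.0   # pA
  noise_sd: 1.0           # pA, added before the 1 kHz low-pass filter
  filter_cutoff: 1000.0   # Hz, 4-pole Butterworth
  sample_rate: 5000.0     # Hz
simulate:
  duration: 5.0       # seconds of seed recording
  seed: 1
prepare:
  window_length: 64
  stride: 64
gan:
  epochs: 200
  batch_size: 32
  learning_rate: 1.0e-4
  seed: 1
generate:
  n_windows: 100
  seed: 7
  crop_fraction: 0.05
evaluate:
  dtw_pairs: 32
  dtw_radius: 1
kinetics:
  k_max: 4
embed:
  method: umap
  seed: 1
clustertest:
  n_permutations: 1000
  seed: 1
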