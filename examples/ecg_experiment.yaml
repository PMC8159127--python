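# Minimal config-driven ECG experiment; run with:  biodimred run examples/ecg_experiment.yaml
dataset: synthetic-ecg
synthetic:
  per_class: 30
  noise_sd: 0.08
  rr_jitter: 0.05
  amp_jitter: 0.10
  baseline_mv: 0.05
methods: [none, cs, le, lpp]
dims: [2, 3, 25]
classifiers:
  - Fine KNN
  - Weighted KNN
  - Cubic SVM
  - Fine Gaussian SVM
  - Linear Discriminant
protocol:
  kfold: 5
seed: 1
output_dir: runs/ecg-demo
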