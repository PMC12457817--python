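# Reduced-scale simulation grid suitable for a laptop / CI run.
mode: simulate
dgms: [simple-1]
sample_sizes: [200, 500]
methods: [aipw, tmle]
libraries: [glm-lasso]
folds: [none, 5]
n_reps: 200
base_seed: 1
output_dir: results/small-grid
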