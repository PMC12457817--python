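# Full-scale grid: 2000 replications per scenario across all mechanisms,
# sample sizes, methods, libraries and fold choices.
# WARNING: this is a long-running batch job (days of single-CPU time with
# the full library); run scenario subsets in parallel processes instead.
mode: simulate
dgms: [simple-1, complex-1a, complex-1b, simple-2, complex-2]
sample_sizes: [200, 500, 1000, 2000]
methods: [aipw, tmle]
libraries: [reduced, full]
folds: [none, 2, 5, 10]
n_reps: 2000
base_seed: 1
output_dir: results/full-grid
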