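# Type-I error of paired difference tests on unstable ring truths
study: difference_type1
n_grid: [200, 1000]
etas: [0.25]
bootstraps: 200
replicates: 50
draws: split   # or: refit (conditional-on-selection), bootstrap (re-selection)
seed: 1
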