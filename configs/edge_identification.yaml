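# Edge-recovery study on covariate-moderated stable truths (scaled down;
# raise replicates to 200 and add n 800/1000 for the full experiment)
study: edge_identification
n_grid: [200, 500]
etas: [0.25, 0.5, 1.0]
replicates: 50
seed: 1
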