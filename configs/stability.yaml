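# Case-dropping centrality stability, stable vs unstable ring truths
study: stability
kinds: [stable, unstable]
n_grid: [1000]
deltas: [0.9, 0.8, 0.7, 0.6, 0.5]
bootstraps: 100
replicates: 20
seed: 1
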