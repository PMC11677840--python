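# Demo run: full pipeline. Contingency and Bliss stages use the packaged
# published counts (reproducing the printed statistics exactly); emergence
# and community stages run on synthetic data generated with the published
# rate ratios and outcome proportions as the true parameters.
out_dir: weevilstats_demo
stages: [simulate, contingency, bliss, emergence, community]
seed: 20220616
destructive_source: packaged
by_block: false
distance_metric: sorensen
n_permutations: 999
dunnett_n_mc: 100000
simulation: {}
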