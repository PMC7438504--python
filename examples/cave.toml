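# Desk-scale example campaign for `cave simulate --config examples/cave.toml`
# Field names mirror cavekit.synthetic_data.CaveConfig; omitted fields take
# package defaults.

genome_length = 4000
n_genes = 6
population_size = 10000
rounds = 5
mutation_rate = 0.25
n_stabilizing = 3
n_neutral_markers = 3
depth = 500
n_background_sites = 10
seed = 7
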