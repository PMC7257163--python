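n_tf: 10
n_gene: 40
tf_tf_arcs: 30
tf_gene_arcs: 120
loop_fraction: 0.25
n_samples: 120
seed: 11
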