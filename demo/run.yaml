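edges: demo/fix/net.tsv
tfs: demo/fix/tfs.txt
expression: demo/fix/expr.tsv
gold: demo/fix/net.tsv
out_dir: demo/out
seed: 11
runs: 50
w: 8
percentile: 25
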