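# Multigeneration exposure design: 3 generations x (2 control + 2 exposed),
# exposure-dependent module rewiring and planted down-regulation; partial
# correlation over the generation grouping.
scenario: experiment2
min_settings: 1
out_dir: results/experiment2
seed: 0
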