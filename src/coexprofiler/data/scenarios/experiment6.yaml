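# Controls plus six exposure groups of four samples; the planted module
# survives only in the high-dose group of one compound.
scenario: experiment6
min_settings: 2
out_dir: results/experiment6
seed: 0
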