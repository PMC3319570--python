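# Three normal-only species settings (8 + 12 + 12 samples) sharing two
# planted correlation modules; plain Pearson networks per setting.
scenario: experiment1
min_settings: 3
out_dir: results/experiment1
seed: 0
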