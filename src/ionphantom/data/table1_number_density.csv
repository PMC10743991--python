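material,atomic_number_density_1e22
ST,8.88
W,10.02
PMMA,8.57
PS,9.81
Resin,8.52
Epoxy,8.16
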