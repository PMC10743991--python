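row,Water,PMMA,PS,ST,Resin,Epoxy
80,0.337,0.373,0.287,0.412,0.279,0.254
100,0.467,0.483,0.450,0.615,0.302,0.322
120,0.661,0.631,0.536,0.872,0.389,0.416
140,0.870,0.890,0.772,1.120,0.597,0.591
Average,0.584,0.594,0.511,0.755,0.392,0.396
S.D.,0.233,0.224,0.202,0.308,0.145,0.146
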