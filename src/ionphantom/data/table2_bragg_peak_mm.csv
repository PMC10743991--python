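row,W,PMMA,PS,ST,Resin,Epoxy
80,40.5,43.2,38.4,46.8,39.1,36.1
100,60.2,64.1,57.6,69.1,57.2,54.2
120,82.5,88.2,78.4,94.5,78.1,75.2
140,108.1,115.2,104,124.5,103.5,99.2
Average,72.825,77.675,69.6,83.725,69.475,66.175
S.D.,25.21,26.89,24.38,28.97,24.01,23.56
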