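material,row,TR,H,C,O,Cl,Mg,N,P,Ca,F,Si,Na,Al
ST,80,3.04,2.4,57.9,20.5,0.2,18.3,1.5,,,,,,
ST,100,3.31,2.3,51.8,19.5,0.2,20.2,7.1,,,,,,
ST,120,1.31,2.5,53.3,19.3,0.1,24.3,1.5,,,,,,
ST,140,2.49,2.3,54.6,21.5,0.2,20.5,1.9,,,,,,
ST,S.D.,0.89,0.1,2.6,1.1,0.1,2.5,2.7,,,,,,
Water,80,1.57,37.2,,64.2,,,,,,,,,
Water,100,1.57,34.7,,66.9,,,,,,,,,
Water,120,3.66,37.9,,63.6,,,,,,,,,
Water,140,3.49,36.9,,64.6,,,,,,,,,
Water,S.D.,1.16,1.4,,1.4,,,,,,,,,
PMMA,80,3.77,25.3,53.6,22.4,,,,,,,,,
PMMA,100,2.86,30.7,46.1,24.7,,,,,,,,,
PMMA,120,2.13,39.6,40.8,20.7,,,,,,,,,
PMMA,140,2.59,27.7,48.5,25.3,,,,,,,,,
PMMA,S.D.,0.69,6.3,5.3,2.1,,,,,,,,,
PS,80,3.18,25.9,75.5,,,,,,,,,,
PS,100,3.93,23.1,78.1,,,,,,,,,,
PS,120,2.78,22.7,78.5,,,,,,,,,,
PS,140,3.31,23.3,77.9,,,,,,,,,,
PS,S.D.,0.48,1.5,1.4,,,,,,,,,,
Resin,80,3.28,21.2,56.3,13.3,3.8,,1.6,3.8,,,,,
Resin,100,3.93,19.5,59.9,13.9,2.3,,1.9,2.5,,,,,
Resin,120,2.79,22.1,54.2,14.2,4.2,,2.1,3.2,,,,,
Resin,140,3.28,22.6,53.3,11.6,5.3,,1.6,5.6,,,,,
Resin,S.D.,0.47,1.4,2.9,1.2,1.3,,0.2,1.3,,,,,
Epoxy,80,3.416,19.2,56.5,14.8,6.6,,,,,,,,
Epoxy,100,3.207,20.4,54.5,15.6,5.9,,,,,,,,
Epoxy,120,2.987,19.4,53.4,11.9,5.3,,,,,,,,
Epoxy,140,3.553,18.1,59.1,11.4,8.5,,,,,,,,
Epoxy,S.D.,0.247,0.9,2.5,2.1,1.4,,,,,,,,
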