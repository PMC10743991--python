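# Liquid water (W) phantom; compound I-value overrides Bragg additivity
name W
density_g_cm3 1.0
I_eV 75
element O atomic_percent=33.3 Ed_eV=28 Eb_eV=3 Es_eV=2
element H atomic_percent=66.6 Ed_eV=10 Eb_eV=3 Es_eV=2
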