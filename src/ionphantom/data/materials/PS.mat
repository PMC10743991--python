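# Polystyrene (PS) phantom
name PS
density_g_cm3 1.06
element H atomic_percent=50 Ed_eV=10 Eb_eV=3 Es_eV=2
element C atomic_percent=50 Ed_eV=28 Eb_eV=3 Es_eV=7.41
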