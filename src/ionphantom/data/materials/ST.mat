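# Soft-tissue (ST) phantom
name ST
density_g_cm3 1.0
element H atomic_percent=54.6 Ed_eV=10 Eb_eV=3 Es_eV=2
element C atomic_percent=32.9 Ed_eV=28 Eb_eV=3 Es_eV=7.41
element N atomic_percent=0.862 Ed_eV=28 Eb_eV=3 Es_eV=2
element O atomic_percent=7.89 Ed_eV=28 Eb_eV=3 Es_eV=2
element Mg atomic_percent=3.63 Ed_eV=25 Eb_eV=3 Es_eV=1.24
element Cl atomic_percent=1.72 Ed_eV=25 Eb_eV=3 Es_eV=2
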