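# Epoxy phantom
name Epoxy
density_g_cm3 1.18
element C atomic_percent=42.2 Ed_eV=28 Eb_eV=3 Es_eV=7.41
element N atomic_percent=2.2 Ed_eV=28 Eb_eV=3 Es_eV=2
element O atomic_percent=8.9 Ed_eV=28 Eb_eV=3 Es_eV=2
element P atomic_percent=2.2 Ed_eV=25 Eb_eV=3 Es_eV=3.27
element Cl atomic_percent=2.3 Ed_eV=25 Eb_eV=3 Es_eV=2
element H atomic_percent=42.2 Ed_eV=10 Eb_eV=3 Es_eV=2
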