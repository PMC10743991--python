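# PMMA at the nominal bulk density (alternate definition; the packaged
# simulation set uses PMMA.mat with 0.95 g/cm3)
name PMMA_bulk
density_g_cm3 1.19
element H atomic_percent=53.3 Ed_eV=10 Eb_eV=3 Es_eV=2
element C atomic_percent=33.3 Ed_eV=28 Eb_eV=3 Es_eV=7.41
element O atomic_percent=13.3 Ed_eV=28 Eb_eV=3 Es_eV=2
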