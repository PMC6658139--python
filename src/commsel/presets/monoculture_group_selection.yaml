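# Manufacturer-only group selection: groups founded from single cells,
# Byproduct saturating, same Resource and T as community selection.
monoculture: true
excess_byproduct: true
init_H: 0
init_M: 1
strategy: top_dog
n_tot: 100
n_cycles: 500
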