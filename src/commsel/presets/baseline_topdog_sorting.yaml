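# Cell sorting fixes Newborn total biomass and species biomass fraction.
strategy: top_dog
reproduction: {method: sort_biomass}
n_tot: 100
n_cycles: 1000
T: 17.0
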