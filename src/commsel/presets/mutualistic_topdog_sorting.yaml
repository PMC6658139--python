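# Mutualistic community: Byproduct inhibits Helper growth (factor exp(-B/B0),
# B0 = 2 K_MB); M benefits H by consuming the inhibitory Byproduct.
strategy: top_dog
reproduction: {method: sort_biomass}
fixed: {B0: 66.666666666666667}
T: 20.0
n_tot: 100
n_cycles: 1000
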