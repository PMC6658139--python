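# Measurement noise at 5% of the ancestral P(T); cell sorting.
strategy: top_dog
reproduction: {method: sort_biomass}
noise_sd_frac: 0.05
n_tot: 100
n_cycles: 1000
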