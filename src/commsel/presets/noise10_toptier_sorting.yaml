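# Measurement noise at 10%: top-tier and cell sorting act in synergy.
strategy: top_tier
n_chosen: 10
reproduction: {method: sort_biomass}
noise_sd_frac: 0.10
n_tot: 100
n_cycles: 1000
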