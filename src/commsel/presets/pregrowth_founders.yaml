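# Cycle-1 Newborns inoculated from a pregrown founder monoculture carrying
# ~3% (typical) null Manufacturers; shared pool across communities.
strategy: top_dog
reproduction: {method: sort_biomass}
pregrowth: true
pregrowth_shared_pool: true
n_tot: 100
n_cycles: 500
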