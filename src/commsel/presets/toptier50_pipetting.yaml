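# Weak selection strength: top 50% of Adults each contribute 2 Newborns.
strategy: top_tier
n_chosen: 50
reproduction: {method: pipetting}
n_tot: 100
n_cycles: 1000
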