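# Top 10% of Adults each contribute an equal number of Newborns.
strategy: top_tier
n_chosen: 10
reproduction: {method: pipetting}
n_tot: 100
n_cycles: 1000
T: 17.0
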