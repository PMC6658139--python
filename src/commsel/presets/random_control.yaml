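# No intercommunity selection: Adults chosen at random; natural selection
# inside communities drives the cost to zero.
strategy: random_control
reproduction: {method: pipetting}
n_tot: 100
n_cycles: 500
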