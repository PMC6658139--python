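# Long maturation (stationary phase): Resource nearly depleted by T.
strategy: top_dog
reproduction: {method: pipetting}
n_tot: 100
n_cycles: 1000
T: 20.0
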