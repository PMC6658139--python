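# Fixed-fold dilution with excess Resource: selection inflates Newborn
# biomass instead of the cost.
strategy: top_dog
reproduction: {method: fixed_fold, fixed_fold_nD: 100}
n_tot: 100
n_cycles: 100
R0: 10.0
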