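# As fast_helper_topdog_pipetting but reproduced by cell sorting: effective
# selection keeps Helper slow enough to coexist with Manufacturer.
strategy: top_dog
reproduction: {method: sort_biomass}
n_tot: 100
n_cycles: 1000
R0: 10.0
growth: {g_Hmax: 0.25, g_Mmax: 0.58, aff_HR: 1.0, aff_MR: 1.0, aff_MB: 0.006}
bounds: {g_Hmax: 0.8}
mutation:
  mutable_set: [g_Hmax, aff_HR, g_Mmax, aff_MR, aff_MB, f_P]
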