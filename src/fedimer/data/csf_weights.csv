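structure,active_space,largest_csf_weight
HC,"63o,64e",0.72
HS,"63o,64e",0.66
HFe,"63o,64e",0.51
HFe2,"63o,64e",0.36
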