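theory,HC,HS,HFe,HFe2
UHF,0.0,-3.7,-21.5,-21.9
UKS-TPSS,0.0,-2.2,-8.7,-7.7
UKS-B3LYP,0.0,-2.1,-10.1,-8.8
UHF/CCSD,0.0,-2.5,-13.7,-13.5
UHF/CCSD(T),0.0,-2.3,-11.9,-10.7
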