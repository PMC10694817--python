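theory,HC,HS,HFe,HFe2
UHF,0.0,203.8,322.5,396.3
UHF/CCSD,0.0,143.7,245.3,253.1
UKS-TPSS/CCSD,0.0,154.9,278.9,305.9
UKS-B3LYP/CCSD,0.0,149.3,269.6,286.8
UHF/CCSD(T),0.0,134.3,190.1,179.9
UKS-TPSS/CCSD(T),0.0,132.6,179.4,163.8
UKS-B3LYP/CCSD(T),0.0,132.4,185.4,167.3
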