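quantity,theory,HC,HS,HFe,HFe2
hs_relative,UHF/CCSD,0.0,164.1,291.6,309.0
hs_relative,UHF/CCSD(T),0.0,158.5,230.7,211.9
s2_hs,CCSD,20.01,20.01,20.32,20.08
bs_relative,UHF/CCSD,0.0,143.7,245.3,253.1
bs_relative,UHF/CCSD(T),0.0,134.3,190.1,179.9
s2_bs,CCSD,3.89,3.78,4.57,4.15
exchange_coupling_cm1,UHF/CCSD,-94.0,-198.2,-342.0,-388.5
exchange_coupling_cm1,UHF/CCSD(T),-112.2,-236.2,-329.9,-281.5
ps_relative,UHF/CCSD,0.0,139.1,231.0,238.2
ps_relative,UHF/CCSD(T),0.0,128.8,177.3,171.1
ps_correction,UHF/CCSD,-4.4,-9.0,-18.7,-19.3
ps_correction,UHF/CCSD(T),-5.2,-10.7,-18.0,-14.0
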