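active_space,quantity,HC,HS,HFe,HFe2
"36o,48e",ccsd_relative,0.0,169.2,241.8,290.7
"36o,48e",ccsdt_offset,-3.4,-4.4,-30.4,-47.0
"36o,48e",dmrg_offset,-6.8,-11.9,-52.8,-79.4
"36o,48e",dmrg_error,0.0,0.0,0.1,0.2
"55o,48e",ccsd_relative,0.0,160.4,232.1,269.5
"55o,48e",ccsdt_offset,-10.8,-13.2,-42.3,-59.2
"55o,48e",dmrg_offset,-16.5,-23.5,-61.0,-90.1
"55o,48e",dmrg_error,0.4,0.4,1.0,3.2
"63o,64e",ccsd_relative,0.0,157.9,270.1,304.2
"63o,64e",ccsdt_offset,-18.3,-21.4,-46.9,-64.6
"63o,64e",dmrg_offset,-27.1,-35.5,-67.2,-92.6
"63o,64e",dmrg_error,0.5,0.5,1.2,2.8
full,ccsd_relative,0.0,143.7,245.3,253.1
full,ccsdt_offset,-214.0,-223.5,-269.2,-287.3
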