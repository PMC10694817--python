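method,basis,average_hartree,HC,HS,HFe,HFe2
UHF,def2-SV(P),-4728.8928,-248.7,-40.7,108.3,181.1
UHF,cc-pVDZ-DK,-4733.8071,-230.7,-26.9,91.9,165.7
UHF,cc-pVTZ-DK,-4733.9598,-221.5,-17.9,83.2,156.1
UHF,cc-pVQZ-DK,-4734.0044,-220.9,-17.9,83.2,155.6
MP2,def2-SV(P),-1.6831,49.5,21.1,-12.7,-57.9
MP2,cc-pVDZ-DK,-2.3403,27.9,-28.5,36.4,-35.9
MP2,cc-pVTZ-DK,-3.3457,-0.6,-52.7,66.2,-13.0
MP2,cc-pVQZ-DK,-3.9214,-5.0,-58.0,71.6,-8.5
MP2,TZ/QZ-CBS,-4.5001,-9.5,-63.3,77.0,-4.1
MP2,DZ/TZ-CBS,-3.9565,-17.9,-67.4,84.3,0.9
CCSD,def2-SV(P),-1.8521,81.3,39.4,-34.7,-86.0
CCSD,cc-pVDZ-DK,-2.4104,70.1,10.0,-7.1,-73.1
CCSD,cc-pVTZ-DK,-3.1171,48.8,-5.5,13.4,-56.7
CCSD,DZ/TZ-CBS,-3.5464,35.8,-14.9,25.8,-46.7
(T),def2-SV(P),-0.0701,26.8,21.1,-16.9,-31.1
(T),cc-pVDZ-DK,-0.0946,34.5,25.0,-20.7,-38.8
(T),cc-pVTZ-DK,-0.1491,34.6,23.8,-18.7,-39.7
(T),DZ/TZ-CBS,-0.1821,34.7,23.0,-17.4,-40.3
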