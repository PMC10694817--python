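section,row,HC,HS,HFe,HFe2,mean,max
composite,uncorrected_tz,0.0,138.6,216.1,197.9,,
composite,mr_correction,0.0,-5.2,-11.4,-19.2,,
composite,basis_correction,0.0,2.1,25.9,21.2,,
composite,total,0.0,135.5,230.6,199.9,0.0,0.0
dft,PBE,0.0,93.1,145.6,87.8,79.8,112.1
dft,BLYP,0.0,90.4,143.3,97.0,78.4,102.9
dft,TPSS,0.0,98.6,161.8,97.4,69.4,102.5
dft,B97-D,0.0,100.2,143.0,115.2,69.2,87.6
dft,r2SCAN,0.0,114.5,163.5,128.3,53.2,71.6
dft,TPSSh,0.0,115.6,200.9,156.0,31.2,43.9
dft,B3LYP*,0.0,113.9,203.4,176.0,24.2,27.2
dft,M06,0.0,135.5,190.6,194.0,15.3,40.0
dft,PBE0,0.0,132.0,239.5,225.0,12.5,25.1
dft,B3LYP,0.0,122.1,223.8,209.1,9.8,13.4
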