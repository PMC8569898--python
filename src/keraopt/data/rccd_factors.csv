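name,units,center,step
KH2PO4,mg/g CFK,0.55,0.15
NH4Cl,mg/g CFK,1.5,0.5
time,day,10.5,3.5
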