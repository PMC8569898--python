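name,units,center,step
K2HPO4,mg/g CFK,1.4,0.4
KH2PO4,mg/g CFK,0.7,0.3
NaCl,mg/g CFK,0.5,0.2
NH4Cl,mg/g CFK,1.0,0.5
MgSO4,mg/g CFK,0.1,0.05
CaCl2,mg/g CFK,0.01,0.005
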