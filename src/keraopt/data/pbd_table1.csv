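run,K2HPO4,KH2PO4,NaCl,NH4Cl,MgSO4,CaCl2,response,sd,predicted
1,1,-1,1,-1,-1,-1,490.0,14.0,370.3
2,1,1,-1,1,-1,-1,760.0,8.5,762.7
3,-1,1,1,-1,1,-1,104.3,13.8,125.7
4,1,-1,1,1,-1,1,1209.1,16.5,1305.5
5,1,1,-1,1,1,-1,712.1,12.6,709.3
6,1,1,1,-1,1,1,93.3,6.5,159.4
7,-1,1,1,1,-1,1,1168.7,17.5,1114.2
8,-1,-1,1,1,1,-1,1228.0,21.6,1218.3
9,-1,-1,-1,1,1,1,1262.0,15.3,1229.8
10,1,-1,-1,-1,1,1,371.3,20.8,328.4
11,-1,1,-1,-1,-1,1,223.6,9.5,190.5
12,-1,-1,-1,-1,-1,-1,240.0,8.8,348.1
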