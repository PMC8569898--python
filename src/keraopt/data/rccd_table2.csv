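run,x_KH2PO4,x_NH4Cl,x_time,KH2PO4,NH4Cl,time,response,sd,rccd_pred,ann_pred,subset,replicate_id,point_type
1,-1,-1,-1,0.400,1.00,7.00,1102.3,0.9,1127.2,1080.3,validation,1,factorial
2,1,-1,-1,0.700,1.00,7.00,1069.4,2.2,1035.9,1069.0,training,1,factorial
3,-1,1,-1,0.400,2.00,7.00,974.9,1.4,947.2,980.2,training,1,factorial
4,1,1,-1,0.700,2.00,7.00,637.6,2.3,658.0,647.9,validation,1,factorial
5,-1,-1,1,0.400,1.00,14.00,1111.1,1.9,1136.2,1149.1,validation,1,factorial
6,1,-1,1,0.700,1.00,14.00,1098.4,1.6,1137.7,1091.6,validation,1,factorial
7,-1,1,1,0.400,2.00,14.00,1189.3,5.1,1225.5,1189.4,validation,1,factorial
8,1,1,1,0.700,2.00,14.00,1059.9,4.6,1029.3,1055.6,training,1,factorial
9,-1.682,0,0,0.298,1.50,10.50,1040.4,1.6,1025.1,1039.9,validation,1,axial
10,1.682,0,0,0.802,1.50,10.50,791.0,2.5,783.3,762.1,validation,1,axial
11,0,-1.682,0,0.550,0.66,10.50,1285.1,2.9,1280.7,1298.1,training,1,axial
12,0,1.682,0,0.550,2.34,10.50,1019.4,1.2,1038.1,1030.5,training,1,axial
13,0,0,-1.682,0.550,1.50,4.61,961.6,1.5,989.0,994.0,validation,1,axial
14,0,0,1.682,0.550,1.50,16.39,1312.1,3.0,1308.7,1337.8,validation,1,axial
15,0,0,0,0.550,1.50,10.50,1601.5,2.1,1626.0,1626.0,validation,1,center
16,0,0,0,0.550,1.50,10.50,1541.7,3.1,1626.0,1626.0,training,1,center
17,0,0,0,0.550,1.50,10.50,1649.4,5.1,1626.0,1626.0,validation,1,center
18,0,0,0,0.550,1.50,10.50,1709.9,3.6,1626.0,1626.0,training,1,center
19,0,0,0,0.550,1.50,10.50,1602.3,3.1,1626.0,1626.0,training,1,center
20,0,0,0,0.550,1.50,10.50,1651.5,3.3,1626.0,1626.0,validation,1,center
21,-1,-1,-1,0.400,1.00,7.00,1081.8,2.9,1127.2,1080.3,training,2,factorial
22,1,-1,-1,0.700,1.00,7.00,1063.4,2.8,1035.9,1069.0,training,2,factorial
23,-1,1,-1,0.400,2.00,7.00,983.1,1.3,947.2,980.2,training,2,factorial
24,1,1,-1,0.700,2.00,7.00,647.5,3.1,658.0,647.9,training,2,factorial
25,-1,-1,1,0.400,1.00,14.00,1181.8,1.6,1136.2,1149.1,validation,2,factorial
26,1,-1,1,0.700,1.00,14.00,1103.1,1.5,1137.7,1091.6,validation,2,factorial
27,-1,1,1,0.400,2.00,14.00,1190.2,4.4,1225.5,1189.4,training,2,factorial
28,1,1,1,0.700,2.00,14.00,1058.7,3.8,1029.3,1055.6,training,2,factorial
29,-1.682,0,0,0.298,1.50,10.50,1039.1,2.0,1025.1,1039.9,validation,2,axial
30,1.682,0,0,0.802,1.50,10.50,761.0,2.6,783.3,762.1,training,2,axial
31,0,-1.682,0,0.550,0.66,10.50,1308.5,1.8,1280.7,1298.1,training,2,axial
32,0,1.682,0,0.550,2.34,10.50,1039.2,1.1,1038.1,1030.5,training,2,axial
33,0,0,-1.682,0.550,1.50,4.61,997.6,1.2,989.0,994.0,training,2,axial
34,0,0,1.682,0.550,1.50,16.39,1338.9,2.4,1308.7,1337.8,training,2,axial
35,0,0,0,0.550,1.50,10.50,1711.6,1.6,1626.0,1626.0,training,2,center
36,0,0,0,0.550,1.50,10.50,1563.2,3.7,1626.0,1626.0,validation,2,center
37,0,0,0,0.550,1.50,10.50,1549.4,5.2,1626.0,1626.0,training,2,center
38,0,0,0,0.550,1.50,10.50,1640.6,3.2,1626.0,1626.0,training,2,center
39,0,0,0,0.550,1.50,10.50,1699.3,4.1,1626.0,1626.0,validation,2,center
40,0,0,0,0.550,1.50,10.50,1588.7,4.5,1626.0,1626.0,validation,2,center
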