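no,z_ratio_monomer,z_ratio_dimer,sum,hplc_ppm
1,1.58,6.27,7.85,820
2,0.00,7.81,7.81,690
3,4.88,3.58,8.46,650
4,3.33,4.88,8.21,590
5,5.02,5.30,10.3,570
6,5.12,0.00,5.12,560
7,6.50,0.00,6.50,510
8,5.00,0.00,5.00,490
9,0.00,5.32,5.32,480
10,0.00,7.82,7.82,470
11,4.62,0.00,4.62,440
12,4.46,0.00,4.46,440
13,0.00,5.56,5.56,380
14,-0.8,0.00,-0.8,130
15,-0.32,0.00,-0.32,120
16,0.65,0.00,0.65,30
17,-15.7,0.00,-15.7,30
18,0.67,0.00,0.67,0
19,0.69,0.00,0.69,0
20,0.64,0.00,0.64,0
21,0.67,0.00,0.67,0
22,0.91,0.00,0.91,0
23,1.20,0.00,1.20,0
24,0.86,0.00,0.86,0
25,1.21,0.00,1.21,0
26,0.87,0.00,0.87,0
27,0.91,0.00,0.91,0
28,1.14,0.00,1.14,0
29,0.65,0.00,0.65,0
30,0.42,0.00,0.42,0
31,0.96,0.00,0.96,0
32,0.81,0.00,0.81,0
33,0.81,0.00,0.81,0
34,0.59,0.00,0.59,0
35,1.38,0.00,1.38,0
36,1.07,0.00,1.07,0
37,-0.25,0.00,-0.25,0
38,1.04,0.00,1.04,0
39,0.65,0.00,0.65,0
40,1.19,0.00,1.19,0
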