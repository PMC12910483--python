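run,x1_coded,x2_coded,x3_coded,cheese_whey_actual,peptone_actual,casein_actual,response
1,0,0,0,50,1.0,0.5,0.0220
2,0,0,0,50,1.0,0.5,0.0220
3,0,-1,1,50,0.5,1.0,0.0176
4,0,1,-1,50,1.5,0.0,0.0102
5,-1,-1,0,20,0.5,0.5,0.0175
6,0,0,0,50,1.0,0.5,0.0220
7,1,0,-1,80,1.0,0.0,0.0192
8,0,1,1,50,1.5,1.0,0.0280
9,0,-1,-1,50,0.5,0.0,0.0260
10,-1,0,1,20,1.0,1.0,0.0181
11,-1,0,-1,20,1.0,0.0,0.0116
12,1,0,1,80,1.0,1.0,0.0231
13,1,1,0,80,1.5,0.5,0.0150
14,1,-1,0,80,0.5,0.5,0.0650
15,-1,1,0,20,1.5,0.5,0.0200
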