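condition,replicate,c0,ct
pH 3,1,1.0,3.105
pH 4,1,1.0,1.12
pH 5,1,1.0,1.08
pH 6,1,1.0,0.637
pH 7,1,1.0,0.415
pH 8,1,1.0,ND
pH 9,1,1.0,ND
20 C,1,1.0,0.99
30 C,1,1.0,1.15
40 C,1,1.0,1.04
50 C,1,1.0,1.025
60 C,1,1.0,0.625
70 C,1,1.0,0.52
daylight,1,1.0,0.26
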