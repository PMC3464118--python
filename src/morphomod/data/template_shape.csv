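landmark,x,y
1,0.00,0.55
2,0.35,0.74
3,0.72,0.80
4,1.05,0.82
5,1.45,1.25
6,1.62,0.95
7,1.95,1.02
8,2.10,0.95
9,1.95,0.70
10,2.05,0.35
11,1.70,0.18
12,1.30,0.12
13,0.90,0.13
14,0.55,0.16
15,0.25,0.25
16,0.05,0.40
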