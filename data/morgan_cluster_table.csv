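cluster,count,min,max
0,84 622,0.12,0.13
1,73 855,0.18,0.19
2,26 780,0.22,0.23
3,39 151,0.08,0.1
4,73 587,0.15,0.16
5,2197,0.29,0.38
6,34 411,0.21,0.22
7,59 637,0.1,0.11
8,83 599,0.13,0.14
9,16 624,0.23,0.25
10,87 920,0.17,0.18
11,21 203,0.06,0.08
12,91 496,0.14,0.14
13,59 584,0.19,0.2
14,76 334,0.11,0.12
15,7938,0.26,0.28
16,85 612,0.14,0.15
17,76 067,0.16,0.17
18,42 065,0.2,0.21
19,5889,0,0.06
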