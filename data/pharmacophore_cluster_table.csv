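cluster,count,min,max
0,93 397,0.03,0.04
1,73 569,0.1,0.11
2,43 931,0.14,0.16
3,89 486,0.07,0.09
4,18 249,0.2,0.23
5,86 610,0,0.01
6,1958,0.27,0.4
7,93 278,0.05,0.06
8,53 014,0.13,0.14
9,35 441,0.16,0.18
10,82 135,0.09,0.1
11,92 748,0.01,0.03
12,9554,0.23,0.27
13,93 130,0.04,0.05
14,92 014,0.06,0.07
15,26 909,0.18,0.2
16,63 148,0.11,0.13
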