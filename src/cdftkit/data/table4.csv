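compound,f_plus_c7,f_plus_c9,p_plus_c7,p_plus_c9
1,0.062,0.057,0.199,0.121
2,0.059,0.054,0.185,0.113
3,0.059,0.054,0.182,0.111
4,0.063,0.054,0.205,0.124
5,0.049,0.047,0.129,0.082
6,0.056,0.053,0.160,0.099
7,0.061,0.056,0.198,0.121
8,0.058,0.054,0.183,0.113
9,0.058,0.053,0.180,0.112
10,0.061,0.053,0.213,0.130
11,0.047,0.046,0.127,0.083
12,0.055,0.053,0.158,0.099
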