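compound,aryl_substituent,n_substituent
1,H,methyl
2,4-Cl,methyl
3,4-Br,methyl
4,4-NMe2,methyl
5,4-CN,methyl
6,4-CF3,methyl
7,H,benzyl
8,4-Cl,benzyl
9,4-Br,benzyl
10,4-NMe2,benzyl
11,4-CN,benzyl
12,4-CF3,benzyl
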