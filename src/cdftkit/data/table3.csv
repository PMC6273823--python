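compound,level_tag,aea_ev,vea_ev,vde_ev
1,basis1,0.932,0.791,1.059
2,basis1,1.263,1.124,1.391
3,basis1,1.280,1.144,1.406
4,basis1,0.578,0.361,0.851
5,basis1,1.856,1.718,1.998
6,basis1,1.512,1.332,1.685
7,basis1,0.939,0.798,1.062
8,basis1,1.264,1.122,1.386
9,basis1,1.282,1.142,1.400
10,basis1,0.531,0.379,0.690
11,basis1,1.848,1.706,1.985
12,basis1,1.510,1.324,1.676
1,basis2_composite,1.398,1.295,1.556
2,basis2_composite,1.669,1.571,1.829
3,basis2_composite,1.707,1.606,1.859
4,basis2_composite,0.977,0.839,1.319
5,basis2_composite,1.902,2.181,2.454
6,basis2_composite,2.002,1.856,2.202
7,basis2_composite,1.407,1.303,1.560
8,basis2_composite,1.672,1.571,1.826
9,basis2_composite,1.709,1.606,1.855
10,basis2_composite,0.970,0.858,1.167
11,basis2_composite,2.271,2.170,2.443
12,basis2_composite,1.999,1.849,2.193
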