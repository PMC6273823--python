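11
toy_enone methyl-vinyl-ketone labels:C7,C8,C9,O9 geometry_tag=opt_neutral
C        0.000000       0.000000       0.000000
C        1.340000       0.000000       0.000000
C        2.075000       1.273057       0.000000
O        1.465000       2.329608       0.000000
C        3.575000       1.273057       0.000000
H       -0.540000       0.935307       0.000000
H       -0.540000      -0.935307       0.000000
H        1.880000      -0.935307       0.000000
H        4.120000       0.329090       0.000000
H        3.960373       1.658431       0.889440
H        3.960373       1.658431      -0.889440
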