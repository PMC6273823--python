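compound,homo_ev,lumo_ev,gap_ev,mu_ev,eta_ev,omega_ev
1,-6.01,-2.09,3.92,-4.05,1.96,4.18
2,-6.22,-2.37,3.85,-4.30,1.92,4.81
3,-6.21,-2.38,3.83,-4.30,1.91,4.81
4,-4.87,-1.51,3.36,-3.19,1.68,3.03
5,-6.54,-2.92,3.62,-4.73,1.81,6.18
6,-6.36,-2.59,3.84,-4.48,1.89,5.31
7,-5.91,-2.06,3.85,-3.99,1.92,4.14
8,-6.11,-2.34,3.77,-4.22,1.88,4.74
9,-6.11,-2.34,3.77,-4.22,1.88,4.74
10,-4.87,-1.50,3.37,-3.18,1.68,3.01
11,-6.41,-2.88,3.53,-4.65,1.77,6.11
12,-6.22,-2.55,3.67,-4.38,1.84,5.21
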