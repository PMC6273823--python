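{
 "mo_coefficients": {
  "alpha": [
   [
    -0.20027402438331923,
    -0.4157005864359127,
    0.2928111770765137,
    -0.4327827185722144,
    -0.4991675035674382,
    -0.5289347322974775
   ],
   [
    -0.6553139603673066,
    -0.31672030449662014,
    -0.06367537688208745,
    -0.2842999013617967,
    0.04602895955495085,
    0.6497015143165698
   ],
   [
    -0.7191382927859594,
    -0.09782115916970191,
    -0.3593408029767319,
    0.5238440775219513,
    -0.1477823711177163,
    -0.32216530356695594
   ],
   [
    -0.2708131842019698,
    0.4209715351312881,
    -0.1558283696363291,
    -0.49915703275547285,
    0.5559426917797703,
    -0.4202368087283139
   ],
   [
    -0.1085723637609876,
    0.7121698240523235,
    -0.09195323164717183,
    -0.2836554384215249,
    -0.6265851726840472,
    0.12614445129546908
   ],
   [
    -0.3252047497345199,
    0.289433557097882,
    0.812280801644243,
    0.3891368551631228,
    0.1415026848506253,
    -0.08556324466251547
   ]
  ]
 },
 "overlap": [
  [
   1.0,
   0.016285403622525008,
   -0.10054772927689601,
   0.012381603184096951,
   -0.07182552871123504,
   0.02134001773946842
  ],
  [
   0.016285403622525008,
   1.0,
   -0.16557800367007902,
   0.05047888337783249,
   0.0048932319876797414,
   0.10772631673627317
  ],
  [
   -0.10054772927689601,
   -0.16557800367007902,
   1.0,
   -0.014290195971978503,
   0.054055081782674375,
   -0.13403978715537004
  ],
  [
   0.012381603184096951,
   0.05047888337783249,
   -0.014290195971978503,
   1.0,
   -0.08331453983169135,
   -0.000832715165212744
  ],
  [
   -0.07182552871123504,
   0.0048932319876797414,
   0.054055081782674375,
   -0.08331453983169135,
   1.0,
   0.035341046338662724
  ],
  [
   0.02134001773946842,
   0.10772631673627317,
   -0.13403978715537004,
   -0.000832715165212744,
   0.035341046338662724,
   1.0
  ]
 ],
 "density": {
  "alpha": [
   [
    0.5973100956535711,
    0.4885166366742052,
    0.1589400594516864,
    -0.3327791122116817,
    -0.6024602465357735,
    0.3653145244083713
   ],
   [
    0.4885166366742052,
    1.0676053831075831,
    1.0502489421488928,
    0.10811971526679412,
    -0.2971090023276882,
    0.13943888392884934
   ],
   [
    0.1589400594516864,
    1.0502489421488928,
    1.3117093520327416,
    0.41913539775723224,
    0.08291162940146402,
    -0.1726623460667657
   ],
   [
    -0.3327791122116817,
    0.10811971526679412,
    0.41913539775723224,
    0.5496785898238395,
    0.687069947644608,
    0.16667325927220386
   ],
   [
    -0.6024602465357735,
    -0.2971090023276882,
    0.08291162940146402,
    0.687069947644608,
    1.0548584265474483,
    0.33348449820414094
   ],
   [
    0.3653145244083713,
    0.13943888392884934,
    -0.1726623460667657,
    0.16667325927220386,
    0.33348449820414094,
    1.6986600278880772
   ]
  ]
 },
 "basis_to_atom": [
  1,
  1,
  2,
  2,
  3,
  3
 ]
}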