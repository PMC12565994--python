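exp_low,exp_high,literature_shift,literature_source,conf1,conf2,conf3,conf4,atom
7.67,7.69,7.532,coumarin,7.71451,7.73565,7.69828,7.73507,H41
7.64,7.65,7.727,coumarin,,7.65159,,7.71932,H34
7.52,7.53,7.498,coumarin,,7.61335,,7.64381,H37
7.52,7.53,7.498,coumarin,7.5168,,7.60374,,H37
7.43,7.45,7.727,coumarin,7.45532,,7.42774,,H34
7.38,7.42,7.285,coumarin,7.39892,7.4337,7.41468,7.44042,H39
7.36,7.37,7.320,coumarin,7.35425,7.38086,7.3116,7.38547,H43
7.25,7.26,7.30,cytisine,,7.33484,,7.3091,H23
7.24,7.25,7.30,cytisine,7.17133,,7.24252,,H23
6.40,6.41,6.45,cytisine,,6.18931,6.18421,6.17365,H21
6.30,6.32,6.45,cytisine,6.1675,,,,H21
6.22,6.23,6.00,cytisine,,6.11264,,6.08142,H26
5.97,5.98,6.00,cytisine,5.8203,,5.88198,,H26
4.61,4.63,3.02,cytisine,4.80551,,4.8375,,H11
4.44,4.46,3.08,cytisine,,4.66794,,4.57591,H7
3.85,3.98,4.13,cytisine,3.9746,3.7792,3.9355,4.04502,H17
3.34,3.72,3.13,cytisine,2.96933,3.49704,2.96097,3.29203,H12
3.34,3.72,3.89,cytisine,3.54296,3.44132,3.57197,3.56477,H16
3.34,3.72,3.02,cytisine,,3.48042,,3.46063,H11
3.34,3.72,3.08,cytisine,3.39088,,3.69225,,H7
3.34,3.72,3.02,cytisine,3.52404,,3.49041,,H6
3.05,3.22,2.91,cytisine,2.84501,2.99421,2.85068,3.00766,H3
3.05,3.22,3.02,cytisine,,3.00641,,2.99382,H6
2.54,2.54,2.35,cytisine,2.38887,,2.41395,,H14
2.5,2.5,,,,,,,solvent
2.33,2.33,2.35,cytisine,,2.23651,,2.26686,H14
2.03,2.03,1.96,cytisine,2.01074,2.00632,2.00363,1.95637,H28
1.95,1.95,1.96,cytisine,1.98077,1.97923,1.97443,1.96155,H29
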