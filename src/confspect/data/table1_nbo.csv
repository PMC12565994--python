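orbital,conformer1,conformer2
BD (1) C10-H11,1.97983,1.97658
BD (1) C10-H12,1.97714,1.97838
BD* (1) C10-H11,0.01446,0.01166
BD* (1) C10-H12,0.02008,0.02318
BD (1) C5-H6,1.97679,1.97558
BD (1) C5-H7,1.97707,1.98012
BD* (1) C5-H6,0.02349,0.02064
BD* (1) C5-H7,0.01115,0.01409
LP (1) O4,1.97772,1.97773
LP (2) O4,1.86858,1.86862
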