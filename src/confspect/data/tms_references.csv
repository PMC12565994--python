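nucleus,isotropic_shielding_ppm
13C,184.32
1H,31.96
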