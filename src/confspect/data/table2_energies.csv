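solvent,conformer,total_energy_ha,relative_kcal_printed
DMSO,1,-1221.865439,0.04
DMSO,2,-1221.865501,0.00
DMSO,3,-1221.864415,0.69
DMSO,4,-1221.864816,0.43
ethanol,1,-1221.864674,0.05
ethanol,2,-1221.864758,0.00
ethanol,3,-1221.863311,0.91
ethanol,4,-1221.863827,0.58
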