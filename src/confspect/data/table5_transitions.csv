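conformer,state,oscillator_strength,wavelength_nm,energy_ev,contributions
1,2,0.2191,316.44,3.9181,94(HOMO-1)->96(LUMO)=79
1,5,0.1676,290.97,4.2610,95(HOMO)->97(LUMO+1)=94
1,7,0.1814,273.25,4.5374,90(HOMO-5)->96(LUMO)=75
1,19,0.0816,217.61,5.6977,95(HOMO)->101(LUMO+5)=64;95(HOMO)->100(LUMO+4)=21
1,26,0.4132,203.71,6.0862,91(HOMO-4)->98(LUMO+2)=23;92(HOMO-3)->98(LUMO+2)=19;93(HOMO-2)->99(LUMO+3)=16;87(HOMO-8)->96(LUMO)=15
2,2,0.2273,316.43,3.9183,94(HOMO-1)->96(LUMO)=79
2,5,0.1756,290.38,4.2698,95(HOMO)->97(LUMO+1)=94
2,7,0.1765,273.05,4.5407,90(HOMO-5)->96(LUMO)=75
2,19,0.0885,217.23,5.7076,95(HOMO)->101(LUMO+5)=69;95(HOMO)->100(LUMO+4)=15
2,26,0.3879,203.66,6.0877,91(HOMO-4)->98(LUMO+2)=26;93(HOMO-2)->99(LUMO+3)=19;87(HOMO-8)->96(LUMO)=15
3,2,0.3041,307.82,4.0278,94(HOMO-1)->96(LUMO)=90
3,4,0.1159,291.46,4.2539,91(HOMO-4)->96(LUMO)=63;95(HOMO)->97(LUMO+1)=22
3,5,0.1031,289.59,4.2813,95(HOMO)->97(LUMO+1)=74;91(HOMO-4)->96(LUMO)=17
3,7,0.0965,269.80,4.5955,90(HOMO-5)->96(LUMO)=70;88(HOMO-7)->96(LUMO)=15
3,20,0.0348,216.94,5.7152,94(HOMO-1)->99(LUMO+3)=41;94(HOMO-1)->98(LUMO+2)=20
3,25,0.3287,203.47,6.0934,91(HOMO-4)->98(LUMO+2)=33;93(HOMO-2)->99(LUMO+3)=17
4,2,0.3324,311.68,3.9779,94(HOMO-1)->96(LUMO)=90
4,5,0.1665,289.44,4.2836,95(HOMO)->97(LUMO+1)=96
4,7,0.1539,271.78,4.5619,90(HOMO-5)->96(LUMO)=74
4,19,0.0925,217.15,5.7097,95(HOMO)->101(LUMO+5)=80
4,26,0.5305,204.23,6.0708,91(HOMO-4)->98(LUMO+2)=41;94(HOMO-1)->98(LUMO+2)=14
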