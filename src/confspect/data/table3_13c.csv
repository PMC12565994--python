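exp_shift,literature_shift,literature_source,conf1,conf2,conf3,conf4,atom
163.49,,,,,163.32039,164.4544,C45
163.32,,,163.93938,163.89789,,,C45
162.15,163.4,cytisine,,,161.12527,161.12232,C19
162.06,163.4,cytisine,161.07417,161.09055,,,C19
157.27,160.63,coumarin,,,,158.30027,C31
156.98,160.63,coumarin,157.63224,157.70973,157.54976,,C31
153.49,153.99,coumarin,154.75016,,,,C44
153.3,153.99,coumarin,,154.81441,154.41463,154.69328,C44
149.49,150.9,cytisine,,152.20028,,152.39242,C24
149.08,150.9,cytisine,151.86926,,151.87505,,C24
141.87,143.48,coumarin,,,,143.92684,C33
141.08,143.48,coumarin,144.86694,145.03269,,,C33
139,138.6,cytisine,,,140.57613,,C33
138.68,138.6,cytisine,137.55998,137.76359,137.57685,137.46474,C22
132.75,131.79,coumarin,132.39204,132.41392,,132.27445,C40
132.68,131.79,coumarin,,,131.95049,,C40
128.91,127.95,coumarin,,128.19128,,,C36
128.75,127.95,coumarin,128.09928,,127.86085,127.99149,C36
124.94,116.56,coumarin,124.14097,124.42785,,125.25192,C32
124.89,116.56,coumarin,,,,123.28139,C38
124.77,124.43,coumarin,123.17321,123.24363,123.14339,,C38
124.03,124.43,coumarin,,,122.88544,,C32
118.24,118.81,coumarin,,117.89503,,117.93348,C35
117.6,118.81,coumarin,117.74929,,117.46083,,C35
116.39,116.70,coumarin,,114.39789,,114.45547,C42
116.29,116.70,coumarin,114.35817,,114.38426,,C42
116.22,116.4,cytisine,113.57598,,113.87905,113.57324,C20
116.1,116.4,cytisine,,113.45574,,,C20
104.87,104.7,cytisine,102.26148,102.52149,102.16693,102.1685,C25
53.25,53.8,cytisine,52.54109,,52.86819,,C5
51.89,53.8,cytisine,,51.18896,,50.97495,C10
48.64,52.8,cytisine,48.32414,,48.3112,,C15
48.42,52.8,cytisine,,48.00117,,47.58756,C15
47.92,49.5,cytisine,,46.41982,,46.84412,C5
47.28,49.5,cytisine,45.20804,,45.15351,,C10
39.5,,,,,,,solvent
34.16,35.4,cytisine,36.39801,,36.28492,,C2
33.7,35.4,cytisine,,35.84356,,35.53579,C2
27.05,27.5,cytisine,,29.33625,,,C13
26.96,27.5,cytisine,28.94628,,28.94226,28.94187,C13
25.06,26.1,cytisine,24.85291,,24.80348,,C27
24.99,26.1,cytisine,,24.72158,,24.69314,C27
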