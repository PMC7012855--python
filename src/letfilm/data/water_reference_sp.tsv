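# Reference electron COLLISION mass stopping powers for liquid water,
# version 1. Transcribed from the ICRU-37/ESTAR tabulation (I = 75 eV,
# includes shell and density-effect corrections). Used only as an
# independent validation fixture for the analytic backend.
# material: water
# energy_keV	S_MeVcm2g
10	22.56
15	16.47
20	13.17
30	9.653
40	7.777
50	6.603
60	5.797
80	4.757
100	4.115
150	3.238
200	2.793
300	2.355
400	2.148
500	2.034
700	1.911
1000	1.849
1500	1.822
2000	1.824
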