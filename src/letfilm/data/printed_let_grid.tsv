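# Published track-average (L_track) and dose-average (L_dose) LET grid for
# the study beams, version 1. keV/um, Delta = 1 keV, combined standard
# uncertainty 0.7% (k=1). Input data for the ratio/report operations.
# film	kind	beam	equivalent_energy_keV	L_track_keV_um	L_dose_keV_um
EBT3	TEF	20kV	13.48	7.12	12.03
EBT3	TEF	50kV	23.56	4.61	10.03
EBT3	TEF	80kV	32.33	4.30	10.71
EBT3	TEF	120kV	47.93	4.40	10.75
EBT3	TEF	160kV	67.39	4.04	9.91
EBT3	TEF	Co60	1044.7	0.51	4.33
MDV3	TEF	20kV	13.48	7.34	12.32
MDV3	TEF	50kV	23.56	4.72	10.19
MDV3	TEF	80kV	32.33	4.32	10.71
MDV3	TEF	120kV	47.93	4.31	10.70
MDV3	TEF	160kV	67.39	4.00	9.97
MDV3	TEF	Co60	1044.7	0.51	4.05
EBT3	SE	20kV	13.48	22.20	23.94
EBT3	SE	50kV	23.56	17.93	21.36
EBT3	SE	80kV	32.33	16.52	20.77
EBT3	SE	120kV	47.93	16.23	20.79
EBT3	SE	160kV	67.39	15.98	20.64
EBT3	SE	Co60	1044.7	3.74	14.14
MDV3	SE	20kV	13.48	22.60	24.36
MDV3	SE	50kV	23.56	18.18	21.69
MDV3	SE	80kV	32.33	16.54	20.99
MDV3	SE	120kV	47.93	16.28	21.02
MDV3	SE	160kV	67.39	16.11	20.88
MDV3	SE	Co60	1044.7	3.67	13.35
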