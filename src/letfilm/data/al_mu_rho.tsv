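# Aluminium mass attenuation coefficients, version 1.
# Total attenuation WITH coherent scattering, transcribed from the standard
# NIST/XCOM tabulation. rho_Al = 2.699 g/cm3. No absorption edges in
# 5-1500 keV for Al, so mu/rho is strictly decreasing on this grid.
# energy_keV	mu_over_rho_cm2_g
5	193.4
6	115.3
8	50.33
10	26.23
15	7.955
20	3.441
30	1.128
40	0.5685
50	0.3681
60	0.2778
80	0.2018
100	0.1704
150	0.1378
200	0.1223
300	0.1042
400	0.09276
500	0.08445
600	0.07802
800	0.06841
1000	0.06146
1250	0.05496
1500	0.05006
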