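# Photon beam-quality registry, version 1 (study beams).
# hvl in mm Al; equivalent_energy_keV is the tabulated equivalent photon
# energy used when reporting LET grids (for Co-60 it is the mean of the two
# gamma lines, adopted verbatim, not derived from an HVL).
# "-" marks a field that does not apply.
# name	tube_potential	added_filter	hvl1_mmAl	hvl2_mmAl	equivalent_energy_keV
20kV	20	0.2794 mm Al	0.25	0.39	13.48
50kV	50	1.0668 mm Al	1.13	1.72	23.56
80kV	80	2.8702 mm Al	2.83	4.17	32.33
120kV	120	7.112 mm Al	6.538	8.36	47.93
160kV	160	5.2324 mm Al + 0.254 mm Cu	10.4	10.75	67.39
Co60	Co60	-	-	-	1044.7
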