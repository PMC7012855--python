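# Elemental data fixture, version 1.
# Z: atomic number; A: standard atomic weight (g/mol);
# I_eV: mean excitation energy recommended for the element when bound in a
# compound (ICRU-37 / Seltzer-Berger in-compound values; metals carry the
# 1.13x condensed-phase factor).
# symbol	Z	A	I_eV
H	1	1.008	19.2
Li	3	6.94	45.2
C	6	12.011	81.0
N	7	14.007	82.0
O	8	15.999	106.0
Na	11	22.990	168.4
Al	13	26.982	187.6
S	16	32.06	180.0
Cl	17	35.45	174.0
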