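# Per-residue physicochemical reference values, v1.
# Columns: residue, category (aliphatic/aromatic/polar_neutral/acidic/basic),
# molecular weight of the free amino acid (Da), pK of the alpha-COOH group,
# pK of the alpha-NH3+ group, pK of the ionizable side group (7.00 placeholder
# when the side chain is not ionizable), isoelectric-point pH, and the
# normalized hydrophobicity indices at pH 2 and pH 7.
residue	category	weight	pk_cooh	pk_nh3	pk_side	pi	hydro_ph2	hydro_ph7
A	aliphatic	89.09	2.34	9.69	7.00	6.00	47	41
C	polar_neutral	121.16	1.96	10.28	8.18	5.07	52	49
D	acidic	133.10	1.88	9.60	3.65	2.77	-18	-55
E	acidic	147.13	2.19	9.67	4.25	3.22	8	-31
F	aromatic	165.19	1.83	9.13	7.00	5.48	92	100
G	aliphatic	75.07	2.34	9.60	7.00	5.97	0	0
H	basic	155.16	1.82	9.17	6.00	7.59	-42	8
I	aliphatic	131.17	2.36	9.60	7.00	6.02	100	99
K	basic	146.19	2.18	8.95	10.53	9.74	-37	-23
L	aliphatic	131.17	2.36	9.60	7.00	5.98	100	97
M	polar_neutral	149.21	2.28	9.21	7.00	5.74	74	74
N	polar_neutral	132.12	2.02	8.80	7.00	5.41	-41	-28
P	aliphatic	115.13	1.99	10.60	7.00	6.30	-46	-46
Q	polar_neutral	146.15	2.17	9.13	7.00	5.65	-18	-10
R	basic	174.20	2.17	9.04	12.48	10.76	-26	-14
S	polar_neutral	105.09	2.21	9.15	7.00	5.68	-7	-5
T	polar_neutral	119.12	2.09	9.10	7.00	5.60	13	13
V	aliphatic	117.15	2.32	9.62	7.00	5.96	79	76
W	aromatic	204.23	2.83	9.39	7.00	5.89	84	97
Y	aromatic	181.19	2.20	9.11	10.07	5.66	49	63
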