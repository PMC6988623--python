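# Eight standard amino-acid physicochemical scales used for the pseudo
# amino-acid composition correlation factors:
#   hydrophilicity      Hopp & Woods (1981)
#   hydrophobicity      Jones (1975)
#   isoelectric_point   Zimmerman et al. (1968)
#   side_chain_volume   Krigbaum & Komoriya (1979)
#   polarity            Grantham (1974)
#   bulkiness           Zimmerman et al. (1968)
#   hydropathy          Kyte & Doolittle (1982)
#   residue_mass        free amino-acid molecular mass (g/mol)
# All scales are z-standardized on load (mean 0 / SD 1 over the 20
# residues), so only their shape matters, not their original units.
property	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
hydrophilicity	-0.5	3.0	0.2	3.0	-1.0	0.2	3.0	0.0	-0.5	-1.8	-1.8	3.0	-1.3	-2.5	0.0	0.3	-0.4	-3.4	-2.3	-1.5
hydrophobicity	0.87	0.85	0.09	0.66	1.52	0.00	0.67	0.10	0.87	3.15	2.17	1.64	1.67	2.87	2.77	0.07	0.07	3.77	2.67	1.87
isoelectric_point	6.00	10.76	5.41	2.77	5.05	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.30	5.68	5.66	5.89	5.66	5.96
side_chain_volume	27.5	105.0	58.7	40.0	44.6	80.7	62.0	0.0	79.0	93.5	93.5	100.0	94.1	115.5	41.9	29.3	51.3	145.5	117.3	71.5
polarity	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
bulkiness	11.50	14.28	12.82	11.68	13.46	14.45	13.57	3.40	13.69	21.40	21.40	15.71	16.25	19.80	17.43	9.47	15.77	21.67	18.03	21.57
hydropathy	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
residue_mass	89.09	174.20	132.12	133.10	121.16	146.15	147.13	75.07	155.16	131.17	131.17	146.19	149.21	165.19	115.13	105.09	119.12	204.23	181.19	117.15
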