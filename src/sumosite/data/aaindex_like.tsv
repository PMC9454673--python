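# Curated table of classical published amino-acid property scales, in the
# one-row-per-property format of the AAindex database (columns in the fixed
# channel order ACDEFGHIKLMNPQRSTVWY). This is a compact curated subset, not
# the full AAindex distribution; any user-supplied table in the same format
# can be loaded in its place.
property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
KYTE_DOOLITTLE_HYDROPATHY	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
HOPP_WOODS_HYDROPHILICITY	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
EISENBERG_CONSENSUS_HYDROPHOBICITY	0.62	0.29	-0.90	-0.74	1.19	0.48	-0.40	1.38	-1.50	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
FAUCHERE_PLISKA_HYDROPHOBICITY	0.31	1.54	-0.77	-0.64	1.79	0.00	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
GRANTHAM_POLARITY	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
GRANTHAM_VOLUME	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
CHOU_FASMAN_HELIX	1.42	0.70	1.01	1.51	1.13	0.57	1.00	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
CHOU_FASMAN_SHEET	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.60	0.74	1.30	1.05	0.89	0.55	1.10	0.93	0.75	1.19	1.70	1.37	1.47
CHOU_FASMAN_TURN	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
ZIMMERMAN_BULKINESS	11.50	13.46	11.68	13.57	19.80	3.40	13.69	21.40	15.71	21.40	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
ZIMMERMAN_ISOELECTRIC_POINT	6.00	5.07	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.30	5.65	10.76	5.68	5.60	5.96	5.89	5.66
RESIDUE_MASS	71.08	103.14	115.09	129.12	147.18	57.05	137.14	113.16	128.17	113.16	131.19	114.10	97.12	128.13	156.19	87.08	101.10	99.13	186.21	163.18
VIHINEN_FLEXIBILITY	0.984	0.906	1.068	1.094	0.915	1.031	0.950	0.927	1.102	0.935	0.952	1.048	1.049	1.037	1.008	1.046	0.997	0.931	0.904	0.929
JANIN_TRANSFER_ENERGY	0.3	0.9	-0.6	-0.7	0.5	0.3	-0.1	0.7	-1.8	0.5	0.4	-0.5	-0.3	-0.7	-1.4	-0.1	-0.2	0.6	0.3	-0.4
CHARTON_POLARIZABILITY	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298
JONES_REFRACTIVITY	4.34	35.77	12.00	17.26	29.40	0.00	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.56	26.66	6.35	11.01	13.92	42.53	31.53
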