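scale	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
hydrophobicity	0.02	-0.42	-0.77	-1.04	0.77	-1.1	-1.14	-0.8	0.26	1.81	1.14	-0.41	1	1.35	-0.09	-0.97	-0.77	1.71	1.11	1.13
flexibility	0.357	0.529	0.463	0.511	0.346	0.493	0.497	0.544	0.323	0.462	0.365	0.466	0.295	0.314	0.509	0.507	0.444	0.305	0.42	0.386
polarizability	0.046	0.291	0.134	0.105	0.128	0.18	0.151	0	0.23	0.186	0.186	0.219	0.221	0.29	0.131	0.062	0.108	0.409	0.298	0.14
free_energy_solution	-0.368	-1.03	0	2.06	4.53	0.731	1.77	-0.525	0	0.791	1.07	0	0.656	1.06	-2.24	-0.524	0	1.6	4.91	0.401
accessible_surface_area	115	225	160	150	135	180	190	75	195	175	170	200	185	210	145	115	140	255	230	155
residue_volume	52.6	109.1	75.7	68.4	68.3	89.7	84.7	36.3	91.9	102	102	105.1	97.7	113.9	73.6	54.9	71.2	135.4	116.2	85.1
steric_parameter	0.52	0.68	0.76	0.76	0.62	0.68	0.68	0	0.7	1.02	0.98	0.68	0.78	0.7	0.36	0.53	0.5	0.7	0.7	0.76
relative_mutability	100	65	134	106	20	93	102	49	66	96	40	56	94	41	56	120	97	18	41	74
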