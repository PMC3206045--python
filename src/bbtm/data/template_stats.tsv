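pdb	n_tm	n_total	n_strands	n_in	n_out	hydro_all	hydro_in	hydro_out
1A0S	172	413	18	84	87	-0.54	-1.66	0.52
1BXW	84	172	8	42	42	-0.05	-1.76	1.66
1E54	139	332	16	70	69	-0.33	-1.8	1.17
1FEP	206	724	22	102	104	-0.67	-2.25	0.87
1I78	102	297	10	50	51	-0.11	-1.99	1.71
1KMO	217	774	22	108	109	-0.94	-2.6	0.7
1NQE	220	549	22	111	109	-0.87	-2.47	0.77
1QD6	124	240	12	59	64	-0.63	-2.64	1.16
1QJ8	75	148	8	35	40	0.2	-1.02	1.27
2MPR	178	427	16	90	87	-0.75	-2.5	1.04
2OMF	153	340	16	76	77	-0.66	-2.38	1.04
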