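mag	group	length_mbp	n_contigs	n_genes	gc_percent	completeness	contamination	sampling_date
MGIIa_c4	MGIIa	1.79	43	1511	51.9	88.5	3.8	2012-03-08
MGIIa_c5	MGIIa	1.93	48	1631	51.5	96.2	0	2012-05-31
MGIIa_c6	MGIIa	1.98	38	1652	50.1	96.2	0	2011-05-26
MGIIa_c10	MGIIa	1.96	49	1619	49.3	96.2	0	2012-05-24
MGIIb_c7	MGIIb	1.39	73	1267	38.2	92.3	0	2012-03-08
MGIIb_c8	MGIIb	1.41	31	1244	38.6	88.5	0	2011-03-21
MGIIb_c11	MGIIb	1.62	25	1448	36.8	96.2	0	2011-04-28
MGIIb_cB	MGIIb	1.33	187	1231	37.4	80.8	0	2011-03-24
Thau_1	Thau	1.14	86	1483	30.9	88.5	0	2011-03-21
Thau_2	Thau	1.07	82	1404	31.3	92.3	0	2010-03-03
Woes_A	Woes	0.71	158	869	36.0	50	0	2010-05-04
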