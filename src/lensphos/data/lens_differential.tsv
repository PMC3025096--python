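accession	protein_name	is_crystallin	novel	designation	frag_start	frag_end	peptide	mz	charge	score	pn_ratio
P53674	Beta-crystallin B1	1	Yes	Ser-32	25	50	GAPPAGTSPSPGTTLAPTTVPITSAK	1229.136	2	94.99	0.32
P53674	Beta-crystallin B1	1	Yes	Ser-81	73	86	RAEFSGECSNLADR	817.847	2	89.04	0.40
P53674	Beta-crystallin B1	1	Yes	Ser-81	73	86	RAEFSGECSNLADR	545.564	3	69.03	0.46
P53674	Beta-crystallin B1	1	Yes	Ser-93	91	110	VRSIIVSAGPWVAFEQSNFR	781.732	3	62.53	5.52
P43320	Beta-crystallin B2	1	No	Thr-91	90	101	RTDSLSSLRPIK	484.894	3	44.22	1.66
P43320	Beta-crystallin B2	1	Yes	Ser-148	146	160	VQSGTWVGYQYPGYR	920.923	2	110.26	2.69
P43320	Beta-crystallin B2	1	Yes	Ser-174	169	188	GDYKDSSDFGAPHPQVQSVR	757.332	3	64.55	2.49
P43320	Beta-crystallin B2	1	Yes	Ser-175	169	188	GDYKDSSDFGAPHPQVQSVR	757.345	3	66.7	2.30
P02511	Alpha-crystallin B	1	No	Ser-19	12	22	RPFFPFHSPSR	485.557	3	68.97	1.89
P02511	Alpha-crystallin B	1	No	Ser-76	73	82	DRFSVNLDVK	636.793	2	66.09	2.09
P07320	Gamma-crystallin D	1	Yes	Ser-21	16	32	HYECSSDHPNLQPYLSR	709.31	3	49.79	0.29
P07320	Gamma-crystallin D	1	Yes	Ser-73	61	77	GDYADHQQWMGLSDSVR	1022.934	2	57.89	0.23
P07320	Gamma-crystallin D	1	Yes	Ser-75	60	77	RGDYADHQQWMGLSDSVR	734.304	3	64.34	0.47
P07320	Gamma-crystallin D	1	Yes	Ser-75	61	77	GDYADHQQWMGLSDSVR	1022.929	2	79.19	0.21
P02489	Alpha-crystallin A	1	Yes	Thr-153	146	157	IQTGLDATHAER	696.33	2	70.14	4.26
P22914	Beta-crystallin S	1	Yes	Thr-6	4	14	TGTKITFYEDK	691.825	2	46.45	0.44
P22914	Beta-crystallin S	1	Yes	Tyr-11	8	19	ITFYEDKNFQGR	799.348	2	74.57	0.48
P07316	Gamma-crystallin B	1	Yes	Ser-75	60	77	RGEYPDYQQWMGLSDSIR	1141.009	2	74.11	0.11
P05813	Beta-crystallin A3	1	Yes	Ser-209	197	212	EWGSHAQTSQIQSIRR	655.3	3	58.65	5.41
P00558	Phosphoglycerate kinase 1	0	Yes	Ser-175	172	184	AHSSMVGVNLPQK	732.304	2	48.65	10.70
Q6ZUU3	Uncharacterized protein C3orf72	0	Yes	Ser-35	32	40	LSESPALVK	512.237	2	39.15	4.84
Q53FA7	Quinone oxidoreductase PIG3	0	No	Ser-260	258	267	RGSLITSLLR	598.324	2	50.37	4.29
P55064	Aquaporin-5	0	Yes	Thr-397	395	403	KKTMELTTR	594.28	2	47.93	3.48
P32119	Peroxiredoxin-2	0	No	Ser-112	110	119	RLSEDYGVLK	630.302	2	40.74	3.18
P40925	Malate dehydrogenase	0	No	Ser-241	239	248	KLSSAMSAAK	545.263	2	43.74	2.46
P14618	Pyruvate kinase isozymes M1/M2	0	Yes	Ser-249	247	255	KASDVHEVR	560.771	2	51.31	2.12
Q13515	Phakinin	0	Yes	Ser-34	32	43	SSSSLESPPASR	642.748	2	52.18	0.46
Q12934	Filensin	0	Yes	Ser-454	452	467	VRSPKEPETPTELYTK	652.331	3	64.65	0.35
P04406	Glyceraldehyde-3-phosphate dehydrogenase	0	No	Thr-184	163	186	VIHDNFGIVEGLMTTVHAITATQK	897.788	3	58.72	0.29
P04792	Heat shock protein beta-1	0	No	Ser-82	80	89	QLSSGVSEIR	578.283	2	43.24	0.15
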