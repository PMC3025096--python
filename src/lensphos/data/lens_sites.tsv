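accession	protein_name	is_crystallin	frag_start	frag_end	peptide	designation
P02511	Alpha-crystallin B	1	12	22	RPFFPFHSPSR	Ser-19
P02511	Alpha-crystallin B	1	12	22	RPFFPFHSPSR	Ser-21
P02511	Alpha-crystallin B	1	57	69	APSWFDTGLSEMR	Ser-59
P02511	Alpha-crystallin B	1	73	82	DRFSVNLDVK	Ser-76
P02511	Alpha-crystallin B	1	124	149	IPADVDPLTITSSLSSDGVLTVNGPR	Ser-139
P02489	Alpha-crystallin A	1	13	21	TLGPFYPSR	Thr-13
P02489	Alpha-crystallin A	1	55	70	TVLDSGISEVRSDRDK	Ser-66
P02489	Alpha-crystallin A	1	79	88	HFSPEDLTVK	Ser-81
P02489	Alpha-crystallin A	1	146	157	IQTGLDATHAER	Thr-148
P02489	Alpha-crystallin A	1	146	157	IQTGLDATHAER	Thr-153
P53674	Beta-crystallin B1	1	25	50	GAPPAGTSPSPGTTLAPTTVPITSAK	Ser-32
P53674	Beta-crystallin B1	1	73	86	RAEFSGECSNLADR	Ser-77
P53674	Beta-crystallin B1	1	73	86	RAEFSGECSNLADR	Ser-81
P53674	Beta-crystallin B1	1	91	110	VRSIIVSAGPWVAFEQSNFR	Ser-93
P53674	Beta-crystallin B1	1	93	110	SIIVSAGPWVAFEQSNFR	Ser-97
P53674	Beta-crystallin B1	1	93	110	SIIVSAGPWVAFEQSNFR	Ser-107
P53674	Beta-crystallin B1	1	188	202	VSSGTWVGYQYPGYR	Ser-189
P53674	Beta-crystallin B1	1	188	202	VSSGTWVGYQYPGYR	Ser-190
P53674	Beta-crystallin B1	1	203	214	GYQYLLEPGDFR	Tyr-204
P43320	Beta-crystallin B2	1	90	101	RTDSLSSLRPIK	Thr-91
P43320	Beta-crystallin B2	1	90	101	RTDSLSSLRPIK	Ser-93
P43320	Beta-crystallin B2	1	91	101	TDSLSSLRPIK	Ser-95
P43320	Beta-crystallin B2	1	109	120	IILYENPNFTGK	Tyr-112
P43320	Beta-crystallin B2	1	109	120	IILYENPNFTGK	Thr-118
P43320	Beta-crystallin B2	1	146	160	VQSGTWVGYQYPGYR	Ser-148
P43320	Beta-crystallin B2	1	169	188	GDYKDSSDFGAPHPQVQSVR	Ser-174
P43320	Beta-crystallin B2	1	169	188	GDYKDSSDFGAPHPQVQSVR	Ser-175
P05813	Beta-crystallin A3	1	46	64	MEFTSSCPNVSERSFDNVR	Thr-49
P05813	Beta-crystallin A3	1	197	211	EWGSHAQTSQIQSIR	Ser-200
P05813	Beta-crystallin A3	1	197	212	EWGSHAQTSQIQSIRR	Ser-209
P53673	Beta-crystallin A4	1	49	71	VLSGAWVGFEHAGFQGQQYILER	Ser-51
P53673	Beta-crystallin A4	1	104	118	DSRLTIFEQENFLGK	Thr-108
P22914	Beta-crystallin S	1	4	14	TGTKITFYEDK	Thr-6
P22914	Beta-crystallin S	1	8	19	ITFYEDKNFQGR	Tyr-11
P22914	Beta-crystallin S	1	85	95	AVHLPSGGQYK	Ser-90
P22914	Beta-crystallin S	1	159	174	KPIDWGAASPAVQSFR	Ser-167
P07316	Gamma-crystallin B	1	60	77	RGEYPDYQQWMGLSDSIR	Ser-75
P07320	Gamma-crystallin D	1	16	32	HYECSSDHPNLQPYLSR	Ser-21
P07320	Gamma-crystallin D	1	61	77	GDYADHQQWMGLSDSVR	Ser-73
P07320	Gamma-crystallin D	1	61	77	GDYADHQQWMGLSDSVR	Ser-75
P07320	Gamma-crystallin D	1	153	163	RYQDWGATNAR	Thr-160
Q12934	Filensin	0	5	11	SYVFQTR	Ser-5
Q12934	Filensin	0	230	239	EVLSHLQAQR	Ser-233
Q12934	Filensin	0	452	467	VRSPKEPETPTELYTK	Ser-454
Q12934	Filensin	0	454	467	SPKEPETPTELYTK	Thr-462
Q12934	Filensin	0	457	467	EPETPTELYTK	Thr-460
Q12934	Filensin	0	605	615	SRSLPEKGPPK	Ser-605
Q12934	Filensin	0	607	615	SLPEKGPPK	Ser-607
Q13515	Phakinin	0	32	43	SSSSLESPPASR	Ser-34
Q13515	Phakinin	0	77	89	ALGISSVFLQGLR	Ser-81
Q13515	Phakinin	0	77	89	ALGISSVFLQGLR	Ser-82
P09972	Fructose-bisphosphate aldolase C	0	116	129	GILAADESVGSMAK	Ser-26
P09972	Fructose-bisphosphate aldolase C	0	130	144	RLSQIGVENTEENRR	Ser-132
P00558	Phosphoglycerate kinase 1	0	172	184	AHSSMVGVNLPQK	Ser-175
P04792	Heat shock protein beta-1	0	80	89	QLSSGVSEIR	Ser-82
Q53FA7	Quinone oxidoreductase PIG3	0	258	267	RGSLITSLLR	Ser-260
P55064	Aquaporin-5	0	395	403	KKTMELTTR	Thr-397
P32119	Peroxiredoxin-2	0	110	119	RLSEDYGVLK	Ser-112
P40925	Malate dehydrogenase	0	239	248	KLSSAMSAAK	Ser-241
P14618	Pyruvate kinase isozymes M1/M2	0	247	255	KASDVHEVR	Ser-249
Q9BR76	Coronin-1B	0	207	214	RGTLVAER	Thr-209
O15144	Actin-related protein 2/3 complex subunit 2	0	135	148	RASHTAPQVLFSHR	Thr-139
Q15149	Plectin-1	0	3783	3793	RLTAEDLFEAR	Thr-3785
Q13449	Limbic system-associated membrane protein	0	89	97	RHSLEYSLR	Ser-91
Q16643	Drebrin	0	140	147	LSSPVLHR	Ser-142
P15153	Ras-related C3 botulinum toxin substrate 2	0	164	174	GLKTVFDEAIR	Thr-167
O43491	Band 4.1-like protein 2	0	400	412	RLSMYGVDLHHAK	Ser-402
P15531	Nucleoside diphosphate kinase A	0	89	105	VMLGETNPADSKPGTIR	Thr-94
P00352	Retinal dehydrogenase 1	0	411	419	FKSLDDVIK	Ser-413
P04075	Fructose-bisphosphate aldolase A	0	29	43	GILAADESTGSIAKR	Ser-39
P04406	Glyceraldehyde-3-phosphate dehydrogenase	0	163	186	VIHDNFGIVEGLMTTVHAITATQK	Thr-184
P30301	Lens fiber major intrinsic protein	0	229	238	SISERLSVLK	Ser-235
Q6ZUU3	Uncharacterized protein C3orf72	0	32	40	LSESPALVK	Ser-35
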