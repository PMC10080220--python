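# Published SPIA results for three mouse knockout-vs-wildtype contrasts
# (Myd88 single null, Myd88/Ager double null, Ager single null) against a
# KEGG mouse pathway snapshot.  Every listed pathway contains the knocked-out
# gene, so the TPKO/FNKO call at a pGFdr cutoff is determined by the printed
# adjusted p-value alone.
contrast	order	pathway_id	name	status	psize	nde	pgfdr
myd88_vs_wt	1	mmu04620	Toll-like receptor signaling pathway	Inhibited	87	36	1.03E-33
myd88_vs_wt	2	mmu05161	Hepatitis B	Inhibited	149	36	1.20E-24
myd88_vs_wt	3	mmu05140	Leishmaniasis	Inhibited	66	23	9.51E-20
myd88_vs_wt	4	mmu05152	Tuberculosis	Inhibited	158	32	2.20E-19
myd88_vs_wt	5	mmu04621	NOD-like receptor signaling pathway	Inhibited	148	30	6.91E-18
myd88_vs_wt	6	mmu05162	Measles	Inhibited	131	28	6.91E-18
myd88_vs_wt	7	mmu05142	Chagas disease (American trypanosomiasis)	Inhibited	99	23	4.43E-15
myd88_vs_wt	8	mmu05169	Epstein-Barr virus infection	Inhibited	185	29	1.16E-14
myd88_vs_wt	9	mmu05164	Influenza A	Inhibited	143	26	1.40E-14
myd88_vs_wt	10	mmu05145	Toxoplasmosis	Inhibited	105	22	2.62E-14
myd88_vs_wt	11	mmu05170	Human immunodeficiency virus 1 infection	Inhibited	194	28	2.16E-13
myd88_vs_wt	12	mmu05135	Yersinia infection	Inhibited	116	22	7.84E-13
myd88_vs_wt	13	mmu05133	Pertussis	Inhibited	67	17	2.36E-12
myd88_vs_wt	14	mmu04064	NF-kappa B signaling pathway	Inhibited	92	18	1.94E-10
myd88_vs_wt	15	mmu05168	Herpes simplex virus 1 infection	Inhibited	340	31	3.64E-10
myd88_vs_wt	16	mmu05132	Salmonella infection	Inhibited	193	24	5.73E-10
myd88_vs_wt	17	mmu05134	Legionellosis	Inhibited	51	13	2.56E-09
myd88_vs_wt	18	mmu05235	PD-L1/PD-1 checkpoint pathway in cancer	Inhibited	84	15	1.38E-08
myd88_vs_wt	19	mmu04010	MAPK signaling pathway	Inhibited	281	25	3.65E-07
myd88_vs_wt	20	mmu05144	Malaria	Inhibited	48	9	1.23E-05
myd88_vs_wt	21	mmu05143	African trypanosomiasis	Inhibited	31	7	0.000126
myd88_ager_vs_wt	1	mmu05170	Human immunodeficiency virus 1 infection	Inhibited	194	61	2.18E-50
myd88_ager_vs_wt	2	mmu04620	Toll-like receptor signaling pathway	Inhibited	87	44	1.24E-45
myd88_ager_vs_wt	3	mmu05169	Epstein-Barr virus infection	Activated	185	53	8.65E-41
myd88_ager_vs_wt	4	mmu05142	Chagas disease (American trypanosomiasis)	Inhibited	99	35	2.30E-29
myd88_ager_vs_wt	5	mmu05162	Measles	Inhibited	131	38	1.42E-28
myd88_ager_vs_wt	6	mmu05161	Hepatitis B	Inhibited	149	40	1.63E-28
myd88_ager_vs_wt	7	mmu05135	Yersinia infection	Inhibited	116	35	1.61E-26
myd88_ager_vs_wt	8	mmu05235	PD-L1/PD-1 checkpoint pathway in cancer	Inhibited	84	31	1.94E-26
myd88_ager_vs_wt	9	mmu05168	Herpes simplex virus 1 infection	Inhibited	340	50	6.55E-24
myd88_ager_vs_wt	10	mmu04621	NOD-like receptor signaling pathway	Activated	148	33	1.24E-20
myd88_ager_vs_wt	11	mmu05140	Leishmaniasis	Inhibited	66	23	3.92E-19
myd88_ager_vs_wt	12	mmu05164	Influenza A	Inhibited	143	31	7.33E-19
myd88_ager_vs_wt	13	mmu05152	Tuberculosis	Inhibited	158	31	1.74E-17
myd88_ager_vs_wt	14	mmu05133	Pertussis	Inhibited	67	21	2.00E-16
myd88_ager_vs_wt	15	mmu05145	Toxoplasmosis	Inhibited	105	23	1.60E-14
myd88_ager_vs_wt	16	mmu04064	NF-kappa B signaling pathway	Inhibited	92	22	5.09E-14
myd88_ager_vs_wt	17	mmu05132	Salmonella infection	Inhibited	193	26	5.18E-11
myd88_ager_vs_wt	18	mmu04933	AGE-RAGE signaling pathway in diabetics	Activated	98	18	1.58E-09
myd88_ager_vs_wt	19	mmu05134	Legionellosis	Inhibited	51	13	7.03E-09
myd88_ager_vs_wt	20	mmu04010	MAPK signaling pathway	Inhibited	281	22	6.66E-06
myd88_ager_vs_wt	21	mmu05144	Malaria	Inhibited	48	9	2.00E-05
myd88_ager_vs_wt	22	mmu05143	African trypanosomiasis	Inhibited	31	7	0.000149
myd88_ager_vs_wt	23	mmu05010	Alzheimer disease	Activated	311	13	0.158326
ager_vs_wt	1	mmu04933	AGE-RAGE signaling pathway in diabetics	Activated	98	10	0.002314
ager_vs_wt	2	mmu05150	Staphylococcus aureus infection	Activated	76	3	0.476408
ager_vs_wt	3	mmu05010	Alzheimer disease	Activated	311	8	0.638874
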