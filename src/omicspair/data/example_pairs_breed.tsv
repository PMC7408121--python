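metabolite_id	gene_id	gene_name	cor_group0	cor_group1	p_interaction	fdr
Rhodamine B	ENSSSCG00000028124	SNRPN	0.776224	-0.54242	3.11e-07	0.1
L-glutamic acid 5-phosphate	ENSSSCG00000010274	SGPL1	0.888112	-0.21456	1.57e-07	0.09
Cystathionine ketimine	ENSSSCG00000010274	SGPL1	0.874126	-0.18719	2.67e-07	0.1
Cystathionine ketimine	ENSSSCG00000040110	Novel_gene	0.923077	-0.11385	1.08e-08	0.02
L-glutamic acid 5-phosphate	ENSSSCG00000038948	ETS2	0.895105	-0.11002	2.66e-08	0.02
L-glutamic acid 5-phosphate	ENSSSCG00000040110	Novel_gene	0.937063	0.010947	1.48e-09	0.01
L-glutamic acid 5-phosphate	ENSSSCG00000014632	FAM160A2	0.951049	0.229885	1.09e-07	0.08
Aloesol	ENSSSCG00000004128	ZC2HC1B	-0.22767	0.048714	4.33e-07	0.1
Theogallin	ENSSSCG00000026442	FAM163B	-0.29772	0.45156	1.69e-07	0.09
Fenamiphos	ENSSSCG00000018649	Novel_gene	-0.68652	0.093596	3.44e-07	0.1
Taraxacolide 1-o-b-d-glucopyranoside	ENSSSCG00000026442	FAM163B	-0.27321	0.648057	1.55e-07	0.09
Proanthocyanidin a2	ENSSSCG00000033688	ZDHHC22	-0.63047	0.32567	4.20e-07	0.1
Fenamiphos	ENSSSCG00000040467	Novel_gene	-0.67251	0.288998	2.25e-08	0.02
L-glutamic acid 5-phosphate	ENSSSCG00000000401	GLS2	-0.85315	0.109469	1.80e-07	0.09
Paracetamol sulfate	ENSSSCG00000000401	GLS2	-0.94406	0.038314	2.87e-07	0.1
L-glutamic acid 5-phosphate	ENSSSCG00000034989	LRRTM2	-0.83916	0.15052	2.17e-08	0.02
Cystathionine ketimine	ENSSSCG00000034989	LRRTM2	-0.79021	0.204707	2.53e-08	0.02
Ketoleucine	ENSSSCG00000026442	FAM163B	-0.5289	0.466886	1.19e-08	0.02
Ganoderenic acid e	ENSSSCG00000034200	SEC22C	-0.85315	0.288998	3.47e-07	0.1
Cystathionine ketimine	ENSSSCG00000000401	GLS2	-0.93007	0.249042	2.92e-09	0.01
Ganoderenic acid e	ENSSSCG00000037595	Novel_gene	-0.85315	0.449371	2.26e-07	0.1
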