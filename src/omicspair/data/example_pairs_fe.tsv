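metabolite_id	gene_id	gene_name	cor_group0	cor_group1	p_interaction	fdr
Pyrocatechol	ENSSSCG00000025106	THNSL2	0.66996	-0.73284	4.72e-08	0.06
2-pyrocatechuic acid	ENSSSCG00000025106	THNSL2	0.645257	-0.68137	7.13e-08	0.08
Ketoleucine	ENSSSCG00000017043	RNF145	0.548419	-0.75735	2.17e-07	0.1
Ketoleucine	ENSSSCG00000025106	THNSL2	0.498024	-0.58088	1.19e-07	0.10
Theogallin	ENSSSCG00000036609	TBXT	0.727273	-0.35049	2.87e-08	0.05
Neodiospyrin	ENSSSCG00000029077	TUBAL3	0.608696	-0.46814	2.63e-08	0.05
Theogallin	ENSSSCG00000025106	THNSL2	0.4417	-0.6152	2.52e-07	0.1
Proanthocyanidin a2	ENSSSCG00000008938	ENAM	0.37954	-0.60539	1.99e-07	0.1
Ketoleucine	ENSSSCG00000036609	TBXT	0.557312	-0.3701	8.78e-08	0.08
Adrenochrome	ENSSSCG00000038441	Novel_gene	0.171485	-0.58088	1.71e-08	0.05
Proanthocyanidin a2	ENSSSCG00000019329	U2	0.052384	-0.66176	1.11e-08	0.05
Levulinic acid	ENSSSCG00000009250	PRKG2	0.075117	-0.54902	1.93e-07	0.1
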