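chr_position	gene	aa_change	delta_editing	pval_mw	padj_bh
chr4:57976234	IGFBP7	K95R	-0.417	0.000015	0.000016
chr13:46090371	COG3	I635V	-0.536	0.000016	0.000017
chr19:7585273	ZNF358	K382R	-0.381	0.000016	0.000017
chr1:160302244	COPA	I164V	-0.416	0.000017	0.000018
chr4:57976286	IGFBP7	R78G	-0.522	0.000019	0.000019
chrX:153579950	FLNA	Q474R	-0.310	0.000027	0.000027
chr4:17805279	DCAF16	I162M	0.059	0.000088	0.000088
chr8:103841636	AZIN1	S367G	-0.081	0.000218	0.004633
chr20:36147572	BLCAP	Y2C	0.090	0.000295	0.005015
chr20:36147563	BLCAP	Q5R	0.063	0.000178	0.005043
chr4:77979680	CCNI	R61G	-0.100	0.000132	0.005610
chr20:36147533	BLCAP	K15R	0.029	0.000464	0.005634
chr19:14593605	GIPC1	T62A	-0.237	0.000458	0.006488
chr12:133682596	ZNF140	Y142H	0.061	0.000998	0.010604
chr14:26917530	NOVA1	S363G	0.099	0.000128	0.010880
chr3:9876560	TTLL3	K419R	0.016	0.001442	0.011143
chr3:58141801	FLNB	Q2103R	-0.228	0.001180	0.011144
chr5:156736808	CYFIP2	K124E	-0.007	0.001350	0.011475
chr15:75646086	NEIL1	K242R	0.182	0.001673	0.011850
chr4:77977164	CCNI	K123R	-0.009	0.002107	0.013777
chr1:12091858	MIIP	S355G	0.018	0.002867	0.017407
chr21:34922801	SON	T422A	-0.146	0.003614	0.020479
chr3:58141791	FLNB	M2100V	-0.116	0.004256	0.022610
chr18:32825609	ZNF397	K314E	0.058	0.004582	0.022910
chr10:79397298	KCNMA1	S35G	-0.051	0.005179	0.024456
chr6:44120349	TMEM63B	Q619R	-0.144	0.006899	0.030864
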