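# Published per-drug validation statistics for the 18 drugs shared between
# the training and external cell-line panels: Pearson r between signature
# score and negative AUC, its printed 95% CI bounds, two-sided p, and the
# published Benjamini-Hochberg FDR (all values at printed precision).
drug	r	ci_upper	ci_lower	p	fdr
Nilotinib	0.6	0.66	0.53	5.95E-38	2.14E-37
Tanespimycin	0.25	0.33	0.16	8.95E-08	1.07E-07
PHA-665752	0.24	0.33	0.15	1.45E-07	1.63E-07
Lapatinib	0.49	0.56	0.42	4.06E-29	9.13E-29
Nutlin-3a (-)	0.26	0.35	0.18	1.11E-08	1.43E-08
Saracatinib	0.22	0.31	0.13	1.38E-06	1.46E-06
Crizotinib	0.45	0.52	0.37	6.06E-24	1.09E-23
Panobinostat	0.61	0.67	0.55	1.83E-48	3.29E-47
Sorafenib	0.42	0.49	0.34	1.45E-20	2.18E-20
Irinotecan	0.65	0.71	0.57	1.11E-35	3.33E-35
Topotecan	0.58	0.64	0.52	3.97E-43	3.57E-42
PD0325901	0.57	0.63	0.51	1.27E-41	7.63E-41
Palbociclib	0.23	0.32	0.14	3.45E-06	3.45E-06
Paclitaxel	0.51	0.57	0.44	2.97E-31	7.64E-31
Selumetinib	0.48	0.55	0.4	1.51E-27	3.03E-27
PLX-4720	0.57	0.63	0.51	7.66E-41	3.45E-40
NVP-TAE684	0.34	0.42	0.26	6.76E-14	9.36E-14
Erlotinib	0.45	0.52	0.37	1.13E-23	1.84E-23
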