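outcome	method	rsid	locus	f_stat	or	ci_lower	ci_upper	pval	q	n_outcome	n_cases
coronary_artery_disease	ivw	.	.	558.5	1.13	0.95	1.35	0.18	4.42	149752	11802
coronary_artery_disease	wald	rs10417628	AMH	.	1.06	0.82	1.37	0.65	.	.	.
coronary_artery_disease	wald	rs13009019	TEX41	.	1.43	1.07	1.91	0.02	.	.	.
coronary_artery_disease	wald	rs16991615	MCM8	.	1.15	0.85	1.57	0.37	.	.	.
coronary_artery_disease	wald	rs11683493	CDCA7	.	0.92	0.67	1.26	0.60	.	.	.
ischemic_stroke	ivw	.	.	65.4	1.11	0.83	1.49	0.48	1.69	17541	4678
ischemic_stroke	wald	rs10417628	AMH	.	1.31	0.78	2.20	0.30	.	.	.
ischemic_stroke	wald	rs13009019	TEX41	.	0.97	0.55	1.70	0.90	.	.	.
ischemic_stroke	wald	rs16991615	MCM8	.	0.85	0.46	1.59	0.62	.	.	.
ischemic_stroke	wald	rs11683493	CDCA7	.	1.35	0.71	2.56	0.35	.	.	.
type_2_diabetes	ivw	.	.	1732.1	0.98	0.87	1.10	0.74	0.54	464389	30052
type_2_diabetes	wald	rs10417628	AMH	.	1.01	0.83	1.23	0.93	.	.	.
type_2_diabetes	wald	rs13009019	TEX41	.	0.91	0.72	1.15	0.43	.	.	.
type_2_diabetes	wald	rs16991615	MCM8	.	0.99	0.77	1.26	0.93	.	.	.
type_2_diabetes	wald	rs11683493	CDCA7	.	1.01	0.79	1.30	0.93	.	.	.
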