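cohort	probe	gene	os_chi2	os_direction	pfi_chi2	pfi_direction
LAML	cg13104385	IL6	5.42	favorable
ACC	cg09257526	IL6R	21.70	unfavorable	18.51	unfavorable
ACC	cg04437762	IL6R	8.68	unfavorable	18.77	unfavorable
ACC	cg05756780	IL6R	4.12	unfavorable
CHOL	cg05756780	IL6R			6.66	unfavorable
BLCA	cg05756780	IL6R			4.72	unfavorable
BRCA	cg09257526	IL6R	5.31	favorable
CESC	cg04437762	IL6R	4.25	unfavorable	5.53	unfavorable
CESC	cg05756780	IL6R	5.28	unfavorable	5.90	unfavorable
UCEC	cg13104385	IL6			7.10	favorable
UCEC	cg05756780	IL6R	5.39	unfavorable	4.90	unfavorable
GBM	cg04437762	IL6R			4.58	favorable
HNSC	cg05756780	IL6R			4.60	unfavorable
KIRC	cg09257526	IL6R			4.93	unfavorable
KIRC	cg05756780	IL6R			4.09	unfavorable
KIRP	cg13104385	IL6	4.34	favorable	5.44	favorable
KIRP	cg04437762	IL6R	10.41	unfavorable	6.56	unfavorable
KIRP	cg05756780	IL6R	7.25	unfavorable
LGG	cg13104385	IL6	21.47	favorable	17.17	favorable
LGG	cg05265849	IL6	8.01	favorable	11.80	favorable
LGG	cg09257526	IL6R	22.81	favorable	19.12	favorable
LGG	cg04437762	IL6R	5.53	favorable
LUAD	cg09257526	IL6R	5.18	unfavorable	6.92	unfavorable
LUAD	cg04437762	IL6R	4.03	unfavorable
LUAD	cg05756780	IL6R	13.40	unfavorable	7.39	unfavorable
LUSC	cg13104385	IL6	4.37	favorable	11.68	favorable
LUSC	cg05265849	IL6			4.17	favorable
SKCM	cg13104385	IL6	5.75	unfavorable
SKCM	cg09257526	IL6R			5.58	favorable
SKCM	cg05756780	IL6R	10.46	favorable	4.74	favorable
MESO	cg09257526	IL6R	5.00	unfavorable	9.43	unfavorable
MESO	cg04437762	IL6R	14.36	unfavorable	27.43	unfavorable
MESO	cg05756780	IL6R			9.02	unfavorable
UVM	cg04437762	IL6R	4.28	unfavorable	7.39	unfavorable
UVM	cg05756780	IL6R	18.55	unfavorable	14.88	unfavorable
PAAD	cg04437762	IL6R			4.29	unfavorable
SARC	cg13104385	IL6			4.15	favorable
SARC	cg05756780	IL6R	5.06	unfavorable
THYM	cg05756780	IL6R	12.19	favorable
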