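cohort	gene	fc	os_chi2	os_direction	pfi_chi2	pfi_direction
LAML	IL6	-2.92			NA	NA
LAML	IL6R	-1.93			NA	NA
LAML	IL6ST				NA	NA
ACC	IL6
ACC	IL6R
ACC	IL6ST	-1.44
CHOL	IL6				5.584	favorable
CHOL	IL6R
CHOL	IL6ST
BLCA	IL6	1.89
BLCA	IL6R	-3.51
BLCA	IL6ST	-3.30			5.39	unfavorable
BRCA	IL6	-7.37
BRCA	IL6R	-2.02
BRCA	IL6ST				7.54	favorable
CESC	IL6	3.04
CESC	IL6R	-2.61
CESC	IL6ST	-3.32
COAD	IL6
COAD	IL6R	-5.70
COAD	IL6ST	-2.56
UCEC	IL6	1.79
UCEC	IL6R	-3.30
UCEC	IL6ST	-3.21
ESCA	IL6	1.62
ESCA	IL6R
ESCA	IL6ST
GBM	IL6	2.66			5.89	unfavorable
GBM	IL6R	1.40
GBM	IL6ST
HNSC	IL6	2.20	4.57	unfavorable
HNSC	IL6R	1.79
HNSC	IL6ST	-2.36	5.42	favorable	5.23	favorable
KICH	IL6	-2.44
KICH	IL6R	-2.21
KICH	IL6ST
KIRC	IL6	1.59	31.46	unfavorable	17.13	unfavorable
KIRC	IL6R	2.00	16.31	favorable	16.09	favorable
KIRC	IL6ST	3.11	9.10	favorable	6.09	favorable
KIRP	IL6		5.78	unfavorable	4.43	unfavorable
KIRP	IL6R
KIRP	IL6ST
DLBC	IL6	6.39
DLBC	IL6R	-10.49
DLBC	IL6ST
LIHC	IL6	-1.58
LIHC	IL6R	-1.46
LIHC	IL6ST
LGG	IL6	-1.92	12.38	unfavorable	6.77	unfavorable
LGG	IL6R		5.04	unfavorable
LGG	IL6ST	1.41
LUAD	IL6	-4.08
LUAD	IL6R		6.50	favorable
LUAD	IL6ST	-1.66	8.90	favorable
LUSC	IL6	-2.40	4.87	unfavorable
LUSC	IL6R	-2.36
LUSC	IL6ST	-3.60
SKCM	IL6
SKCM	IL6R	1.42
SKCM	IL6ST
MESO	IL6	-2.80
MESO	IL6R	-3.50	4.20	favorable	11.79	favorable
MESO	IL6ST
UVM	IL6	-11.90	7.52	unfavorable	4.19	unfavorable
UVM	IL6R	-1.46
UVM	IL6ST
OV	IL6	2.88
OV	IL6R
OV	IL6ST	-2.54
PAAD	IL6	3.21
PAAD	IL6R
PAAD	IL6ST	1.42
PCPG	IL6
PCPG	IL6R	-3.97
PCPG	IL6ST	-1.74
PRAD	IL6
PRAD	IL6R	-1.87
PRAD	IL6ST
READ	IL6
READ	IL6R	-5.66
READ	IL6ST	-2.43
SARC	IL6		5.74	favorable
SARC	IL6R	-15.19	6.92	favorable
SARC	IL6ST
STAD	IL6	2.18	4.57	unfavorable
STAD	IL6R	-1.56			4.59	unfavorable
STAD	IL6ST				4.16	unfavorable
TGCT	IL6	5.19
TGCT	IL6R	3.47
TGCT	IL6ST
THYM	IL6
THYM	IL6R	-11.77	3.87	unfavorable
THYM	IL6ST	2.69
THCA	IL6	-2.20	3.66	unfavorable
THCA	IL6R	-1.59
THCA	IL6ST
UCS	IL6	1.52
UCS	IL6R	-5.38
UCS	IL6ST	-2.89
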