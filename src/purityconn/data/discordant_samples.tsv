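sample_prefix	methylation_cluster	reeval	purity_pct	mean_conn_px12_cay	vhl_status	mrna_subtype	loss_3p
TCGA-A3-3385	papillary	ccRCC	95.94	-0.36	high_mutation	m1	no
TCGA-CZ-5469	papillary	ccRCC	77.92	-0.22	none	m4	yes
TCGA-B0-5098	papillary	unconventional-ccRCC	85.19	-0.11	none	missing	yes
TCGA-B0-5100	papillary	unconventional-ccRCC	79.56	-0.37	methylation	m3	no
TCGA-B2-5636	chromophobe	unconventional-ccRCC	65.98	0.15	methylation	m3	missing
TCGA-B4-5378	chromophobe	unconventional-ccRCC	82.88	-0.39	missing	missing	no
TCGA-B8-4621	papillary	unconventional-ccRCC	70.24	0.0	none	m4	no
TCGA-B8-A54K	chromophobe	unconventional-ccRCC	85.54	0.0	methylation	missing	no
TCGA-BP-4760	chromophobe	unconventional-ccRCC	79.31	-0.20	methylation	missing	no
TCGA-DV-5567	chromophobe	unconventional-ccRCC	83.9	0.0	high_mutation	m3	no
TCGA-DV-5576	chromophobe	unconventional-ccRCC	77.64	-0.43	none	m3	no
TCGA-DV-A4VZ	chromophobe	unconventional-ccRCC	84.06	0.0	methylation	missing	no
TCGA-AK-3433	chromophobe	non-ccRCC	92.15	0.14	missing	missing	yes
TCGA-AK-3440	chromophobe	non-ccRCC	97.65	0.0	none	missing	no
TCGA-AK-3453	chromophobe	non-ccRCC	99.47	-0.30	none	missing	no
TCGA-B0-4688	papillary	non-ccRCC	72.77	0.0	missing	missing	no
TCGA-B0-4696	chromophobe	non-ccRCC	82.65	-0.12	missing	missing	yes
TCGA-B0-4699	chromophobe	non-ccRCC	76.9	0.29	missing	missing	no
TCGA-B0-5083	chromophobe	non-ccRCC	72.74	0.0	none	missing	missing
TCGA-B0-5117	chromophobe	non-ccRCC	88.39	0.0	none	missing	no
TCGA-B0-5707	papillary	non-ccRCC	80.36	0.15	none	missing	missing
TCGA-B8-5546	papillary	non-ccRCC	90.52	0.40	none	m1	no
TCGA-CJ-5681	papillary	non-ccRCC	86.31	0.16	none	m1	yes
TCGA-EU-5907	papillary	non-ccRCC	91.83	-0.17	high_mutation	missing	yes
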