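gene	wt_tri	mt_tri	ka_wt	ka_mt	log_ratio	ddg_bind	score_difference	experimental_outcome
HSD17B4	AKL	AEL	2.544	0.065	1.592	5.138	-37.8	loss
HSD17B4	AKL	PKL	2.544	1.915	0.123	0.154	-4.4	no_change
DAO	SHL	FHL	1.859	0.186	1.000	7.910	-18.9	loss
ACOX2	SKL	STL	8.015	0.646	1.094	3.800	-25.0	loss
EHHADH	SKL	GKL	6.444	1.424	0.655	0.920	-8.5	loss
EHHADH	SKL	NKL	6.444	2.027	0.502	1.687	-5.8	loss
PPP4R4	SNP	SNL	0.065	1.808	-1.444	0.359	33.9	gain
RFLNA	ATL	AKL	0.059	5.826	-1.995	-0.723	31.1	gain
ARHGAP1	SGL	SRL	0.047	1.209	-1.410	-2.432	28.5	gain
HPGDS	TKL	SKL	1.792	5.110	-0.455	1.397	22.2	no_change
GLTP	YKV	CKV	0.108	0.020	0.738	-0.877	10.1	no_change
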