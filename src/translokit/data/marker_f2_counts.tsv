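f2_line	translocation	marker	n_plants	homozygous_wt	heterozygous_tl	homozygous_tl	ratio	chi2_printed
WT-a x MT-a	T6-10	Chr6+Chr6^10	237	51	125	61	1:2:1	1.557
WT-a x MT-a	T6-10	Chr10+Chr10^6	237	51	125	61	1:2:1	1.557
WT-b x MT-b	T1-5+T4-8	Chr1+Chr1^5	182	52	89	41	1:2:1	1.417
WT-b x MT-b	T1-5+T4-8	Chr5+Chr5^1	182	49	91	42	1:2:1	0.538
WT-b x MT-b	T1-5+T4-8	Chr4+Chr4^8	182	54	88	40	1:2:1	2.352
WT-b x MT-b	T1-5+T4-8	Chr8+Chr8^4	182	49	89	44	1:2:1	0.363
WT-c x MT-c	T1-5-11	Chr1+Chr1^5	173	44	82	47	1:2:1	0.572
WT-c x MT-c	T1-5-11	Chr5+Chr5^1	173	44	82	47	1:2:1	0.572
WT-c x MT-c	T1-5-11	Chr5+Chr5^11	173	37	93	43	1:2:1	1.393
WT-c x MT-c	T1-5-11	Chr11+Chr11^5	173	37	93	43	1:2:1	1.393
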