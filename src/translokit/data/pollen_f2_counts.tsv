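f2_line	n_plants	normal_pollen	sterile_pollen	ratio	chi2_printed
WT-a x MT-a	237	112	125	1:1	0.713
WT-b x MT-b	182	46	136	1:3	0.007
WT-c x MT-c	173	65	108	1:3	14.583
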