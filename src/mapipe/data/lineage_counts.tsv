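genotype	functional_domain	functional_class	sbs	indels	rate_printed	fold_printed
MSH2_genomic	genomic_wt	wild_type	1	0	4.8e-10	1
msh2_null	null	null_like	7	140	7.1e-08	215
msh2-A618V	structural_integrity	null_like	8	109	5.7e-08	171
msh2-R657G	structural_integrity	null_like	6	141	7.1e-08	215
msh2-L183P	structural_integrity	null_like	7	143	7.2e-08	220
msh2-C195Y	structural_integrity	null_like	15	158	8.4e-08	253
msh2-C345F	structural_integrity	null_like	16	180	9.5e-08	287
msh2-D621G	structural_integrity	null_like	12	144	7.5e-08	228
msh2-P640T	structural_integrity	null_like	10	125	6.5e-08	198
msh2-R542L	dna_binding	null_like	4	135	6.7e-08	203
msh2-D524Y	dna_binding	null_like	14	151	8.0e-08	242
msh2-G688D	atpase	null_like	15	139	7.4e-08	225
msh2-G693R	atpase	null_like	9	146	7.5e-08	227
msh2-S695P	atpase	null_like	14	159	8.4e-08	253
msh2-S742F	atpase	null_like	9	156	8.0e-08	242
msh2-T743K	atpase	null_like	5	147	7.3e-08	223
msh2-G770R	atpase	null_like	7	147	7.4e-08	225
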