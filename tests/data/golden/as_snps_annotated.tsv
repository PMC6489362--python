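chrom	pos	significant_marks	allelic_ratio	gwas_status	gwas_source	gwas_r2	traits	eqtl_genes
chr1	152176	H3K27ac	0.7568	unlinked	.	.	.	.
chr1	179272	H3K4me3	0.7714	unlinked	.	.	.	.
chr2	14001	H3K4me3	0.8378	ld_proxy	rs1003	0.8464	Obesity-related traits	GENED
chr2	149406	CTCF	0.8824	direct_hit	.	.	Type 2 diabetes	GENEA
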