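chrom	pos	pwm	tf	strand	placement_start	score_allele1	score_allele2	delta	dnase	tf_chip	cage	tf_expressed	chromatin_state	replication_domain	functionality_score	candidate_functional
chr1	152176	SYN_EGR1	EGR1	+	152174	0.886698	0.853669	0.033028	0	0	0	1	Quies	late	1.0000	0
chr1	152176	SYN_CTCF	CTCF	+	152170	0.886698	0.853669	0.033028	0	0	0	1	Quies	late	1.0000	0
chr1	152176	SYN_KLF5	KLF5	+	152172	0.915045	0.235173	0.679872	0	0	0	0	Quies	late	0.0000	0
chr1	179272	SYN_EGR1	EGR1	+	179266	0.938624	0.888940	0.049684	0	0	0	1	Quies	late	1.0000	0
chr1	179272	SYN_CTCF	CTCF	+	179270	0.948073	0.925572	0.022502	0	0	0	1	Quies	late	1.0000	0
chr1	179272	SYN_KLF5	KLF5	+	179267	0.929175	0.883094	0.046081	0	0	0	0	Quies	late	0.0000	0
chr2	14001	SYN_EGR1	EGR1	-	14000	0.823960	0.879491	0.055530	1	0	0	1	Quies	early	2.2500	0
chr2	14001	SYN_CTCF	CTCF	+	13999	0.938624	0.883094	0.055530	1	0	0	1	Quies	early	2.2500	0
chr2	14001	SYN_KLF5	KLF5	+	13998	0.962203	0.916122	0.046081	1	0	0	0	Quies	early	1.2500	0
chr2	149406	SYN_EGR1	EGR1	+	149402	1.000000	0.277651	0.722349	1	1	1	1	TssA	late	5.0000	1
chr2	149406	SYN_CTCF	CTCF	-	149403	0.935021	0.258752	0.676268	1	0	1	1	TssA	late	4.0000	1
chr2	149406	SYN_KLF5	KLF5	+	149405	0.916122	0.906673	0.009449	1	0	1	0	TssA	late	3.0000	0
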