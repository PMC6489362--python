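trait	n_as_snps	n_loci
Obesity-related traits	1	1
Type 2 diabetes	1	1
Total	2	1
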