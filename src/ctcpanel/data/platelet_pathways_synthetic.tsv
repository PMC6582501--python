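pathway_id	gene_id
platelet_alpha_granule_lumen	CLU
platelet_alpha_granule_lumen	SPARC
platelet_alpha_granule_lumen	SRGN
platelet_alpha_granule_lumen	PF4
platelet_alpha_granule_lumen	TGFB1
platelet_degranulation	CLU
platelet_degranulation	SPARC
platelet_degranulation	SRGN
platelet_degranulation	PF4
platelet_degranulation	TGFB1
platelet_degranulation	THBS1
platelet_degranulation	VWF
platelet_degranulation	SELP
platelet_degranulation	FN1
platelet_degranulation	PPBP
platelet_degranulation	ITGB3
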