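gene_a	gene_b	confidence
PF4	CCL5	0.962
PF4	CLU	0.915
PF4	SPARC	0.941
PF4	SRGN	0.909
PF4	PPBP	0.988
CCL5	SRGN	0.731
CCL5	CCR5	0.996
CLU	SPARC	0.752
TGFB1	SPARC	0.812
TGFB1	THBS1	0.934
THBS1	SPARC	0.773
THBS1	ITGB3	0.912
PECAM1	ITGB3	0.742
EGF	EGFR	0.991
GPX1	SOD1	0.684
GIMAP4	GIMAP5	0.623
SRGN	CLU	0.655
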