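patient_id	diagnosis	histology_stage	unicapture_count	quadcapture_count
001	NSCLC	Adenocarcinoma, IV; bone	0	0
002	NSCLC	Adenocarcinoma, IV; bone	0	0
003	NSCLC	Adenocarcinoma, IV; brain	0	1
004	NSCLC	Adenocarcinoma, IV; bone	0	0
006	NSCLC	Adenocarcinoma, II; lymph nodes	0	1
007	NSCLC	Squamous, IV; brain metastasis	0	0
008	NSCLC	Adenocarcinoma, IV; lymph node metastasis	84	0
010	NSCLC	Adenocarcinoma, IV; brain, bone, adrenal, subcutaneous tissue	1	0
011	NSCLC	Adenocarcinoma, IV; adrenal	1	0
012	NSCLC	Adenocarcinoma, IV; liver	1	0
005	SCLC	Extensive; liver	1	1
009	SCLC	Extensive; liver, adrenal, bone	1615	1491
013	SCLC	Extensive; lymph nodes	84	62
014	SCLC	Extensive; bone, liver, brain	12	111
015	SCLC	Extensive; bone	0	0
016	SCLC	Limited stage	0	2
018	SCLC	Limited stage	0	0
019	SCLC	Extensive; liver	4007	3810
020	SCLC	Limited stage	0	6
021	SCLC	Extensive	22	16
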