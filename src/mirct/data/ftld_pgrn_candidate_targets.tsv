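mirna_id	gene_symbol
miR-922	BAI3
miR-548b-5p	BAI3
miR-548c-5p	BAI3
miR-571	GK
miR-548b-5p	GK
miR-548c-5p	GK
miR-922	SLC23A2
miR-548b-5p	SLC23A2
miR-548c-5p	SLC23A2
miR-516a-3p	GTDC1
miR-571	GTDC1
miR-548b-5p	CNR1
miR-548c-5p	CNR1
miR-548b-5p	FAM134B
miR-548c-5p	FAM134B
miR-548b-5p	HS2ST1
miR-548c-5p	HS2ST1
miR-548b-5p	MYT1L
miR-548c-5p	MYT1L
miR-548b-5p	NCAM1
miR-548c-5p	NCAM1
miR-548b-5p	TMEM135
miR-548c-5p	TMEM135
miR-922	ATP8A1
miR-922	KCNAB1
miR-922	PTPRD
miR-922	RASA1
miR-922	REEP1
miR-922	SNCA
miR-516a-3p	A2BP1
miR-516a-3p	ASTN1
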