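mirna	target_gene	mark	annotation	class	abundance_tp10m	cleavage_site	location	specific_family
Soy_2	Glyma17g02170		F-box protein	II	15	67	CDS	0
Soy_3	Glyma07g39750	#	PPR-containing protein	II	19	1633	CDS	0
Soy_3	Glyma17g01050	#	PPR-containing protein	III	19	1659	CDS	0
Soy_4	Glyma04g03110		oxidoreductase	IV	13	447	CDS	0
Soy_5	Glyma12g30680		60S ribosomal protein	III	17	643	5'UTR	0
Soy_7	Glyma16g25990		G-protein	II	15	1780	CDS	0
Soy_7	Glyma19g37520		copper ion binding protein	IV	15	684	CDS	0
Soy_8	Glyma19g28990	#	tubulin	III	17	920	CDS	0
Soy_8	Glyma16g04420	#	polyubiquitin protein	III	17	931	CDS	0
Soy_9	Glyma11g37920		HD-ZIP transcription factor	IV	19	629	CDS	0
Soy_10	Glyma19g22900		methyltransferase	IV	17	936	5'UTR	0
Soy_11	Glyma05g26750	#	endomembrane protein	II	27	1407	CDS	0
Soy_11	Glyma08g09740	#	endomembrane protein	II	27	1416	CDS	0
Soy_11	Glyma17g14370		ribosomal protein	IV	19	257	CDS	0
Soy_16	Glyma09g30740	#	PPR-containing protein	I	14	616	CDS	0
Soy_16	Glyma09g30680	#	PPR-containing protein	IV	14	460	CDS	0
Soy_17	Glyma02g14400		expressed protein	III	15	955	5'UTR	0
Soy_19	Glyma19g35560	#	Heat shock cognate protein	IV	47	282	CDS	0
Soy_19	Glyma03g32850	#	Heat shock cognate protein	IV	47	480	CDS	0
Soy_21	Glyma15g04010	*	Transcription factor IIA	IV	14	694	CDS	0
Soy_21	Glyma13g41390	*	Transcription factor IIA	IV	14	1348	5'UTR	0
Soy_21	Glyma19g03770		transferase protein	IV	14	746	CDS	0
Soy_21	Glyma03g41900		bHLH family transcription factor	II	55	1184	CDS	0
Soy_22	Glyma19g41650		peptide chain release factor	IV	15	1258	5'UTR	0
Soy_25	Glyma05g33260		suppressor of gene silencing	II	30	555	CDS	0
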