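gene_id	gene_name	disease
ENSG00000232978	RP11-146N23.4	Aortic Stenosis
ENSG00000273226	RP11-513M16.8	Aortic Stenosis
ENSG00000274220	RP11-77K12.9	CAD
ENSG00000233471	KRT18P62	CAD
ENSG00000246889	AP000487.5	CAD
ENSG00000259999	RP11-252K23.1	CAD
ENSG00000262583	RP11-77K12.5 / TMEM231P1	CAD
ENSG00000250474	WBP1LP2	CAD
ENSG00000178803	ADORA2A-AS1	CAD
ENSG00000201151	SNORD56	CAD
ENSG00000244691	RPL10AP1	CAD
ENSG00000248278	SUMO2P17	CAD
ENSG00000258978	HIF1AP1	CAD
ENSG00000128262	POM121L9P	CAD
ENSG00000283828	RP11-98F14.12	Cardiac Arrhythmia
ENSG00000238228	OR7E7P	Cardiac Arrhythmia
ENSG00000250899	RP11-253E3.3	Cardiac Arrhythmia
ENSG00000271146	RP11-479F13.1	Cardiac Arrhythmia
ENSG00000252072	RNA5SP320	Cardiac Arrhythmia
ENSG00000269125	RP11-98F14.11	Cardiac Arrhythmia
ENSG00000270723	RPL23AP92	Cardiac Arrhythmia
ENSG00000274415	RP11-433J22.2	Cardiac Arrhythmia
ENSG00000272954	KB-1440D3.13	Cardiomyopathy
ENSG00000226677	IGBP1P1	Cardiomyopathy
ENSG00000274281	RP11-326N17.2	Cardiomyopathy
ENSG00000223534	HLA-DQB1-AS1	Cardiomyopathy
ENSG00000227409	ZMYM4-AS1	Cardiomyopathy
ENSG00000229391	HLA-DRB6	Cardiomyopathy
ENSG00000252042	Y RNA	Cardiomyopathy
ENSG00000259345	RP11-624L4.1	Cardiomyopathy
ENSG00000263786	RP11-649A18.4	Cardiomyopathy
ENSG00000275293	Metazoa SRP	Cardiomyopathy
ENSG00000249994	CTD-2383I20.1	Myocardial Infarction
ENSG00000225124	RPL23AP36	Myocardial Infarction
ENSG00000272750	RP11-378J18.8	Myocardial Infarction
ENSG00000229116	RP11-20J15.3	Myocardial Infarction
ENSG00000265215	MIR4269	Myocardial Infarction
ENSG00000266936	CTC-215O4.4	Myocardial Infarction
ENSG00000233579	KRT8P15	Myocardial Infarction & CAD
ENSG00000270001	RP11-218C14.8	Myocardial Ischemia
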