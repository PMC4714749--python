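!gaf-version: 2.1
DB	g1	G1		GO:0000004	REF:1	IDA		F	gene one		protein	taxon:1	20200101	DB
DB	g1	G1		GO:0000002	REF:1	IEA		F	gene one		protein	taxon:1	20200101	DB
DB	g2	G2		GO:0000003	REF:1	IMP		F	gene two		protein	taxon:1	20200101	DB
DB	g3	G3	NOT	GO:0000004	REF:1	IDA		F	gene three		protein	taxon:1	20200101	DB
DB	g3	G3		GO:0000001	REF:1	TAS		F	gene three		protein	taxon:1	20200101	DB
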