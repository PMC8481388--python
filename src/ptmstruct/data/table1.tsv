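# Transcribed list of cancer-specific modified peptides (identification table).
# site = 1-based position of the modified residue within the peptide.
# raw_metrics keeps the source table's fused PSM/identification/coverage/ion string verbatim;
# the numeric PSM and identification counts are typographically ambiguous there and left unparsed.
group	gene	protein	peptide	ptm_kind	site	raw_metrics
OC	A1AT	Alpha-1-antitrypsin	KQINDYVEK	acetyl-K	1	13117551B/8Y
OC	A1AT	Alpha-1-antitrypsin	TDTSHHDQDHPTFNKITPNLAEFAFSLYR	acetyl-K	15	13117550B/6Y
OC	ALBU	Albumin	EQLKAVMDDFAAFVEK	acetyl-K	4	9417320B/7Y
OC	ALBU	Albumin	NYAEAKDVFLGMFLYEYAR	acetyl-K	6	45425310B/6Y
OC	ALBU	Albumin	RHPYFYAPELLFFAK	phospho-Y	6	61846763B/6Y
OC	ALBU	Albumin	VFDEKPLVEEPQNLIK	acetyl-K	5	61846760B/5Y
OC	APOA2	Apolipoprotein A-II	EPCVESLVSQYFQTVTDYGK	phospho-S	6	296631B/6Y
OC	CO3	Complement C3	KVLLDGVQNPR	acetyl-K	1	16132310B/5Y
OC	HV307	Ig heavy chain V-III region CAM	DDSKNTLYLQMNSLR	acetyl-K	4	114120B/9Y
OC	IGHA1	Ig alpha-1 chain C region	SGNTFRPEVHLLPPPSEELALNELVTLTCLAR	phospho-S	16	9013630B/7Y
OC	KNG1	Kininogen-1	ETTCSKESNEELTESCETK	phospho-T	2	139217B/9Y
OC	TRFE	Serotransferrin	MDAKMYLGYEYVTAIR	acetyl-K	4	14519300B/8Y
BC	ALBU	Albumin	EQLKAVMDDFAAFVEK	acetyl-K	4	46527431B/7Y
BC	ALBU	Albumin	KVPQVSTPTLVEVSR	acetyl-K	1	46527430B/5Y
BC	ALBU	Albumin	NYAEAKDVFLGMFLYEYAR	acetyl-K	6	68748790B/8Y
BC	APOA1	Apolipoprotein A-I	QLNLKLLDNWDSVTSTFSK	acetyl-K	5	4316734B/10Y
BC	TRFE	Serotransferrin	KSASDLTWDNLK	acetyl-K	1	35738660B/9Y
BC	TRFE	Serotransferrin	MDAKMYLGYEYVTAIR	acetyl-K	4	15917342B/8Y
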