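# Transcribed per-peptide solvent-accessibility table: average area accessible to the
# solvent (A^2) of the modified amino acid and of its active environment, before
# (intact) and after (ptm) mounting of the modification.
# Decimal commas of the source were normalized to points at packaging.  Apparent
# typographic oddities were kept verbatim (env_intact 163 / env_ptm 349.85 for the
# HV307 row; the breast-cancer NYAEA... peptide printed without its final R and
# localized to "Helix" versus "Connection" in the ovarian section).
# helices / motives columns are unresolvable for some rows and left blank or n/d.
group	gene	peptide	localization	pdb_structures	aa_intact	aa_ptm	env_intact	env_ptm	helices	motives
OC	A1AT	KQINDYVEK	Helix	35	119.99	167.54	335.14	364.17	4	1
OC	A1AT	TDTSHHDQDHPTFNKITPNLAEFAFSLYR	Connection	23	109.78	153.36	346.66	377.32
OC	ALBU	EQLKAVMDDFAAFVEK	Helix	156	113.03	135.71	441.31	431.30	30	4
OC	ALBU	KVPQVSTPTLVEVSR	Helix	172	21.53	7.29	320.08	312.11	3
OC	ALBU	NYAEAKDVFLGMFLYEYAR	Connection	16	82.02	108.97	294.16	305.17	3
OC	ALBU	RHPYFYAPELLFFAK	Helix	163	22.49	31.01	165.83	154.03	3
OC	ALBU	VFDEFKPLVEEPQNLIK	Helix	162	131.78	179.83	278.90	316.22	2
OC	APOA2	EPCVESLVSQYFQTVTDYGK	Helix	56	69.47	101.31	498.39	501.38	4	n/d
OC	CO3	YFKPGMPFDLMVFVTNPDGSPAYR	Helix	51	13.86	16.87	134.78	110.51		n/d
OC	HV307	DDSKNTLYLQMNSLR	Connection	21	126.05	177.73	163	349.85	0	0
OC	IGHA1	SGNTFRPEVHLLPPPSEELALNELVTLTCLAR	Helix	34	103.55	168.88	318.55	361.30	3	1
BC	ALBU	NYAEAKDVFLGMFLYEYA	Helix	16	82.02	108.97	294.16	305.17	30	3
BC	ALBU	EQLKAVMDDFAAFVEK	Helix	156	113.03	135.71	441.31	431.30	4
BC	APOA1	QLNLKLLDNWDSVTSTFSK	Helix	61	36.75	184.78	317.5	348.78	8	n/d
BC	TRFE	KSASDLTWDNLK	Helix	32	111.32	155.53	322.75	349.13	22	12
BC	TRFE	MDAKMYLGYEYVTAIR	Connection	72	64.48	104.60	260.24	279.48	22	12
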