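name	pfam	expected_orf	pattern	threshold
helicase	pfam00910	orf1	GxPG[ST]GK[ST]	10
peptidase	pfam12381	orf1	Hx[LIVM]xxGxCG[FY]x[LIVM]	9
rdrp	pfam00680	orf1	SGxxxTxxxNSx[LIVM]xxxxxxxxxxYGDD	16
capsid	pfam08762	orf2	[DN]WTR[LIVM]xxP[FY]xxGRG	14
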