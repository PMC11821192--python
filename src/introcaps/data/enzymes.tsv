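# Default restriction enzyme table (editable).
# Recognition patterns use IUPAC codes; cut_offset counts bases from the
# pattern 5' end to the cut on the scanned strand (RsaI = GT^AC).
name	pattern	cut_offset
RsaI	GTAC	2
AluI	AGCT	2
MboI	GATC	0
TaqI	TCGA	1
HinfI	GANTC	1
DdeI	CTNAG	1
HaeIII	GGCC	2
MseI	TTAA	1
EcoRI	GAATTC	1
HindIII	AAGCTT	1
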