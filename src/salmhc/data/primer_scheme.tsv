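gene	role	label	sequence
UBA	forward	UBA1_F	CTGGGAATAGGCCTTCTACAT
UBA	forward	UBA4_F	GGCATCTGCAGTAACCCACT
UBA	reverse	UBA_R	TCCAGATACTTCTTCAGCCAC
DAA	forward	DAA_F	TGCTGGCAGGTGTATGCAGAA
DAA	reverse	DAA_R	GGTGAAATCAGCGTTGGGGT
DAB	forward	DAB1_F	ATGTCGATGTCTATCTTCTG
DAB	forward	DAB2_F	TTCTGCGTTTCCCTGACCC
DAB	reverse	DAB_R	GTACCAGTCCCCGTTAGCCAG
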