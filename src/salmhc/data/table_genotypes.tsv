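animal	gene	allele_1	count_1	allele_2	count_2	forward_primer
AS1	DAA	DAA*06:01	39861	DAA*04:01	37247	DAA_F
AS2	DAA	DAA*06:01	29496	DAA*03:02	28281	DAA_F
AS3	DAA	DAA*01:02	14569	DAA*09:01	12123	DAA_F
AS5	DAA	DAA*06:01	38290			DAA_F
AS6	DAA	DAA*02:01	21935	DAA*09:01	19807	DAA_F
AS7	DAA	DAA*06:01	31665	DAA*02:01	29058	DAA_F
AS8	DAA	DAA*04:01	25961	DAA*01:02	22389	DAA_F
AS9	DAA	DAA*03:02	27650	DAA*09:01	22549	DAA_F
AS10	DAA	DAA*04:01	90816			DAA_F
AS1	DAB	DAB*09:01	63791	DAB*06:01	20621	DAB2_F
AS2	DAB	DAB*20:01	30852	DAB*06:01	17876	DAB1_F
AS3	DAB	DAB*07:01	10179	DAB*08:01	7127	DAB1_F
AS5	DAB	DAB*06:01	11545	AS5DABs2	9933	DAB2_F
AS6	DAB	DAB*09:01	10396	DAB*02:01	9420	DAB1_F
AS7	DAB	DAB*02:01	71872	DAB*06:01	24758	DAB2_F
AS8	DAB	DAB*09:02	41329	DAB*08:01	29683	DAB2_F
AS9	DAB	DAB*07:01	16301	DAB*20:01	10525	DAB1_F
AS10	DAB	DAB*09:01	74482			DAB1_F
AS1	UBA	UBA*07:01	30927			UBA1_F
AS2	UBA	AS2UBAs1	46437	AS2UBAs2	33647	UBA1_F
AS3	UBA	UBA*07:01	13465	UBA*13:01	12935	UBA1_F
AS5	UBA	AS5UBAs1	22247	AS5UBAs2	20661	UBA4_F
AS6	UBA	UBA*13:01	18686	UBA*02:01	3956	UBA1_F
AS7	UBA	AS7UBAs1	25193	UBA*20:01	6454	UBA1_F
AS8	UBA	UBA*13:01	30959	UBA*06:01	24959	UBA1_F
AS9	UBA	UBA*13:01	20357	AS9UBAs2	14112	UBA1_F
AS10	UBA	UBA*34:01	71332			UBA1_F
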