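# Synthetic stand-in coding intervals for the 59-gene ACMG SF v2.0 panel.
# Chromosome assignments are the genes' true chromosomes; start/end are
# constructed placeholders adequate for simulation, not real exon bounds.
1	5000000	5001500	CACNA1S
1	5006000	5008200	CACNA1S
1	5400000	5401500	LMNA
1	5406000	5408200	LMNA
1	5800000	5801500	MUTYH
1	5806000	5808200	MUTYH
1	6200000	6201500	PCSK9
1	6206000	6208200	PCSK9
1	6600000	6601500	RYR2
1	6606000	6608200	RYR2
1	7000000	7001500	SDHB
1	7006000	7008200	SDHB
1	7400000	7401500	SDHC
1	7406000	7408200	SDHC
1	7800000	7801500	TNNT2
1	7806000	7808200	TNNT2
10	5000000	5001500	ACTA2
10	5006000	5008200	ACTA2
10	5400000	5401500	BMPR1A
10	5406000	5408200	BMPR1A
10	5800000	5801500	PTEN
10	5806000	5808200	PTEN
10	6200000	6201500	RET
10	6206000	6208200	RET
11	5000000	5001500	KCNQ1
11	5006000	5008200	KCNQ1
11	5400000	5401500	MEN1
11	5406000	5408200	MEN1
11	5800000	5801500	MYBPC3
11	5806000	5808200	MYBPC3
11	6200000	6201500	SDHAF2
11	6206000	6208200	SDHAF2
11	6600000	6601500	SDHD
11	6606000	6608200	SDHD
11	7000000	7001500	WT1
11	7006000	7008200	WT1
12	5000000	5001500	MYL2
12	5006000	5008200	MYL2
12	5400000	5401500	PKP2
12	5406000	5408200	PKP2
13	5000000	5001500	ATP7B
13	5006000	5008200	ATP7B
13	5400000	5401500	BRCA2
13	5406000	5408200	BRCA2
13	5800000	5801500	RB1
13	5806000	5808200	RB1
14	5000000	5001500	MYH7
14	5006000	5008200	MYH7
15	5000000	5001500	ACTC1
15	5006000	5008200	ACTC1
15	5400000	5401500	FBN1
15	5406000	5408200	FBN1
15	5800000	5801500	SMAD3
15	5806000	5808200	SMAD3
15	6200000	6201500	TPM1
15	6206000	6208200	TPM1
16	5000000	5001500	MYH11
16	5006000	5008200	MYH11
16	5400000	5401500	TSC2
16	5406000	5408200	TSC2
17	5000000	5001500	BRCA1
17	5006000	5008200	BRCA1
17	5400000	5401500	TP53
17	5406000	5408200	TP53
18	5000000	5001500	DSC2
18	5006000	5008200	DSC2
18	5400000	5401500	DSG2
18	5406000	5408200	DSG2
18	5800000	5801500	SMAD4
18	5806000	5808200	SMAD4
19	5000000	5001500	LDLR
19	5006000	5008200	LDLR
19	5400000	5401500	RYR1
19	5406000	5408200	RYR1
19	5800000	5801500	STK11
19	5806000	5808200	STK11
19	6200000	6201500	TNNI3
19	6206000	6208200	TNNI3
2	5000000	5001500	APOB
2	5006000	5008200	APOB
2	5400000	5401500	COL3A1
2	5406000	5408200	COL3A1
2	5800000	5801500	MSH2
2	5806000	5808200	MSH2
2	6200000	6201500	MSH6
2	6206000	6208200	MSH6
22	5000000	5001500	NF2
22	5006000	5008200	NF2
3	5000000	5001500	MLH1
3	5006000	5008200	MLH1
3	5400000	5401500	MYL3
3	5406000	5408200	MYL3
3	5800000	5801500	SCN5A
3	5806000	5808200	SCN5A
3	6200000	6201500	TGFBR2
3	6206000	6208200	TGFBR2
3	6600000	6601500	TMEM43
3	6606000	6608200	TMEM43
3	7000000	7001500	VHL
3	7006000	7008200	VHL
5	5000000	5001500	APC
5	5006000	5008200	APC
6	5000000	5001500	DSP
6	5006000	5008200	DSP
7	5000000	5001500	KCNH2
7	5006000	5008200	KCNH2
7	5400000	5401500	PMS2
7	5406000	5408200	PMS2
7	5800000	5801500	PRKAG2
7	5806000	5808200	PRKAG2
9	5000000	5001500	TGFBR1
9	5006000	5008200	TGFBR1
9	5400000	5401500	TSC1
9	5406000	5408200	TSC1
X	5000000	5001500	GLA
X	5006000	5008200	GLA
X	5400000	5401500	OTC
X	5406000	5408200	OTC
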