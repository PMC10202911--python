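# Top-ranked genes per scoring metric, in printed order (disease score order).
# Symbols are stored exactly as printed; see typo_normalization.tsv.
metric	rank	gene
Degree	1	IL6
Degree	2	ASPM
Degree	3	TTK
Degree	4	KIF20A
Degree	5	TPX2
Degree	6	CENPF
Degree	7	UBE2C
Degree	8	CCNB1
Degree	9	CDK1
Degree	10	NUF2
Degree	11	KIF11
Degree	12	KIF4A
Degree	13	DLGAP5
Degree	14	TOP2A
Degree	15	MAD2L1
Degree	16	PBK
Degree	17	BIRC5
MCC	1	ASPM
MCC	2	BIRC5
MCC	3	BUB1B
MCC	4	CNNB1
MCC	5	CCNB2
MCC	6	CDC20
MCC	7	CDK1
MCC	8	CENPF
MCC	9	DLGAP5
MCC	10	KIAA0101
MCC	11	KIF11
MCC	12	KIF20A
MCC	13	KIF4A
MCC	14	MAD2L1
MCC	15	MELK
MCC	16	NDC80
MCC	17	NUF2
MCC	18	NUSAP1
MCC	19	PBK
MCC	20	RRM2
MCC	21	TOP2A
MCC	22	TPX2
MCC	23	TTK
MCC	24	UBE2C
MCC	25	ZWINT
DMNC	1	HMMR
DMNC	2	CDKN3
DMNC	3	CEP55
DMNC	4	CENPF
DMNC	5	BUB1B
DMNC	6	UBE2C
DMNC	7	CCNB2
DMNC	8	RRM2
DMNC	9	NUSAP
DMNC	10	NDC80
DMNC	11	KIAA0101
DMNC	12	TOP2A
DMNC	13	ZWINT
DMNC	14	CDC20
DMNC	15	MAD2L1
DMNC	16	PBK
DMNC	17	MELK
MNC	1	IL6
MNC	2	KIF20A
MNC	3	DLGAP5
MNC	4	ASPM
MNC	5	KIF4A
MNC	6	KIF11
MNC	7	NUF2
MNC	8	CDK1
MNC	9	CCNB1
MNC	10	TPX2
MNC	11	BIRC5
MNC	12	TTK
Clustering coefficient	1	ABCA3
Clustering coefficient	2	ACADL
Clustering coefficient	3	BCHE
Clustering coefficient	4	CA4
Clustering coefficient	5	CDCA7
Clustering coefficient	6	DKK2
Clustering coefficient	7	FAM107A
Clustering coefficient	8	FHL1
Clustering coefficient	9	GINS1
Clustering coefficient	10	GPX3
Clustering coefficient	11	HS6ST2
Clustering coefficient	12	LIFR
Clustering coefficient	13	PTPRB
Clustering coefficient	14	RASIP1
Clustering coefficient	15	SCARA5
Clustering coefficient	16	SCN7A
Clustering coefficient	17	SDPR
Clustering coefficient	18	SFTA3
Clustering coefficient	19	SOX7
Clustering coefficient	20	TMPRSS4
Clustering coefficient	21	WIF1
Betweenness	1	IL6
Betweenness	2	BMP2
Betweenness	3	UBE2C
Betweenness	4	CAV1
Betweenness	5	SOX2
Betweenness	6	SPP1
Betweenness	7	AQP4
Betweenness	8	CDH5
Betweenness	9	NPNT
Betweenness	10	AGER
Bottleneck	1	IL6
Bottleneck	2	UBE2C
Bottleneck	3	SOX2
Bottleneck	4	CAV1
Bottleneck	5	BMP2
Bottleneck	6	SPP1
Bottleneck	7	AGER
Bottleneck	8	CDH5
Bottleneck	9	AQP4
Bottleneck	10	NPNT
Bottleneck	11	SFTPD
Eccentricity	1	KIF26B
Eccentricity	2	ITGA8
Eccentricity	3	HHIP
Eccentricity	4	NPNT
Eccentricity	5	AGER
Eccentricity	6	THBS2
Eccentricity	7	SFTPC
Eccentricity	8	KIF4A
Eccentricity	9	HMGB3
Eccentricity	10	SCGB1A1
Eccentricity	11	KIF20A
Eccentricity	12	KIF11
Eccentricity	13	SFTPD
Eccentricity	14	IL6
Eccentricity	15	CDH5
Eccentricity	16	CLIC5
Eccentricity	17	GPC3
Eccentricity	18	COL6A6
Eccentricity	19	AGTR1
Eccentricity	20	SFTPB
Closeness	1	IL6
Closeness	2	UBE2C
Closeness	3	SOX2
Closeness	4	CAV1
Closeness	5	SPP1
Closeness	6	BMP2
Closeness	7	CDH5
Closeness	8	DLGAP5
Closeness	9	CDK1
Closeness	10	CCNB1
Closeness	11	BIRC5
Radiality	1	IL6
Radiality	2	SOX2
Radiality	3	CAV1
Radiality	4	BMP2
Radiality	5	SPP1
Radiality	6	CDH5
Radiality	7	UBE2C
Radiality	8	CLDN5
Radiality	9	CEACAM5
Radiality	10	TEK
Stress	1	IL6
Stress	2	SOX2
Stress	3	BMP2
Stress	4	CAV1
Stress	5	SPP1
Stress	6	UBE2C
Stress	7	CDH5
Stress	8	SCGB1A1
Stress	9	AQP4
Stress	10	GPC3
EPC	1	Il6
EPC	2	TOP2A
EPC	3	CDC20
EPC	4	CDK1
EPC	5	UBE2T
EPC	6	ZWINT
EPC	7	CDKN3
EPC	8	NUF2
EPC	9	KIF4A
EPC	10	RRM2
EPC	11	KIF11
EPC	12	NEK2
EPC	13	ASPM
EPC	14	NUSAP1
EPC	15	KIF20A
EPC	16	HMMR
EPC	17	ANLN
EPC	18	DLGAP5
EPC	19	NDC80
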