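# Overall top disease-correlated genes ranked by individual AUC
# (19 printed rows). Symbols as printed; see typo_normalization.tsv.
gene	auc	logfc	fdr
AGER	0.8979	-2.13691	4.45E-84
CA4	0.8952	-1.50475	1.70E-89
RASIP1	0.8899	-1.20962	3.52E-65
CAV1	0.8741	-1.41913	5.23E-55
FAM107A	0.8731	-1.94635	1.39E-72
CDH5	0.8725	-1.40895	3.69E-63
TEK	0.8724	-1.45729419	2.13E-73
CLDN5	0.8697	-1.21244	1.24E-56
CLIC5	0.8686	-2.03743	4.42E-61
SPP1	0.8647	2.334613	6.97E-60
KIF26B	0.8636	1.293536	2.98E-48
PTRB	0.8604	-1.653827903	1.57E-61
SOX7	0.8560	-1.599491119	2.45E-48
SDPR	0.8542	-1.861487998	2.53E-56
TOP2A	0.8516	2.014367341	4.75E-58
TMPRSS4	0.8459	1.634397285	1.70E-44
AGTR1	0.8446	-1.503517517	5.72E-52
CDCA7	0.8417	1.650737609	6.42E-52
GPX3	0.8416	-1.388971807	9.69E-46
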