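# Scoring metrics with panel Integrated AUC and mean individual-gene AUC,
# in printed order.
metric	integrated_auc	mean_individual_auc
Clustering coefficient	0.8770	0.8159
Bottleneck	0.8609	0.8012
Betweenness	0.8517	0.8091
Eccentricity	0.8409	0.8017
Stress	0.8179	0.7919
DMNC	0.8136	0.7860
MCC	0.8114	0.7874
EPC	0.8030	0.7959
Degree	0.7875	0.7877
MNC	0.7748	0.7890
Radiality	0.7904	0.8100
Closeness	0.6366	0.7986
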