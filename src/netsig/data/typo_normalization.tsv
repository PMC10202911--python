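# Symbol corrections applied when fixtures are loaded with
# normalize_typos=True. KIAA0101 (now PCLAF) is deliberately kept as printed.
printed	corrected
CNNB1	CCNB1
NUSAP	NUSAP1
PTRB	PTPRB
Il6	IL6
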