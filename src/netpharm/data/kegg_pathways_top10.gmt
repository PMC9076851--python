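hsa05200	Pathways in cancer	GSK3B	JUN	HSP90AA1	MMP2	PTGS2	MMP9	EGFR	RELA	VEGFA	CASP9	IL6	CASP3	AKT1	MAPK1	HRAS	TP53	BCL2L1	MAPK3
hsa04151	PI3K-Akt signaling pathway	GSK3B	HSP90AA1	NOS3	EGFR	RELA	VEGFA	CASP9	IL6	AKT1	MAPK1	HRAS	TP53	MCL1	BCL2L1	MAPK3
hsa05205	Proteoglycans in cancer	MMP2	MAPK14	ESR1	TNF	MMP9	EGFR	VEGFA	CASP3	AKT1	MAPK1	HRAS	TP53	MAPK3
hsa04010	MAPK signaling pathway	JUN	IL1B	CASP3	MAPK1	AKT1	MAPK14	HRAS	TNF	TP53	RELA	EGFR	MAPK3
hsa04668	TNF signaling pathway	IL6	JUN	IL1B	CASP3	MAPK1	AKT1	MAPK14	PTGS2	TNF	MMP9	RELA	MAPK3
hsa05161	Hepatitis B	CASP9	IL6	JUN	CASP3	MAPK1	AKT1	HRAS	TNF	TP53	MMP9	RELA	MAPK3
hsa04915	Estrogen signaling pathway	HSP90AA1	JUN	NOS3	MMP2	MAPK1	AKT1	HRAS	ESR1	MMP9	EGFR	MAPK3
hsa05164	Influenza A	CASP9	GSK3B	IL6	JUN	IL1B	MAPK1	AKT1	MAPK14	TNF	RELA	MAPK3
hsa05215	Prostate cancer	CASP9	GSK3B	HSP90AA1	MAPK1	AKT1	HRAS	TP53	RELA	EGFR	MAPK3
hsa05160	Hepatitis C	GSK3B	MAPK1	AKT1	MAPK14	HRAS	TNF	TP53	RELA	EGFR	MAPK3
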