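# Edgecounts of 93 osteoporosis-related targets in the compound-target PPI network
gene	protein_name	edgecount
AKT1	Protein kinase	67
TNF	Tumor necrosis factor	59
VEGFA	Vascular endothelial growth factor A	58
IL6	Interleukin-6	56
MAPK3	Mitogen-activated protein kinase 3	54
CASP3	Caspase-3	54
IL1B	Interleukin-1 beta	53
TP53	Cellular tumor antigen p53	53
JUN	Transcription factor AP-1	50
EGFR	Epidermal growth factor receptor	49
PTGS2	Prostaglandin G/H synthase 2	45
HSP90AA1	Heat shock protein HSP 90-alpha	45
ESR1	Estrogen receptor	45
MMP9	Matrix metalloproteinase-9	44
HRAS	GTPase HRas	40
NOS3	Nitric oxide synthase, endothelial	39
SIRT1	NAD-dependent protein deacetylase sirtuin-1	37
BCL2L1	Bcl-2-like protein 1	35
RELA	Transcription factor p65	34
MAPK1	Mitogen-activated protein kinase 1	33
MAPK14	Mitogen-activated protein kinase 14	33
MMP2	72 kDa type IV collagenase	32
GSK3B	Glycogen synthase kinase-3 beta	31
CASP9	Caspase-9	31
MCL1	Induced myeloid leukemia cell differentiation protein Mcl-1	31
VCAM1	Vascular cell adhesion protein 1	29
SOD1	Superoxide dismutase	27
CDK2	Cyclin-dependent kinase 2	25
PTPN1	Tyrosine-protein phosphatase non-receptor type 1	24
PIK3CA	PI3-kinase subunit alpha	24
HSPA5	Endoplasmic reticulum chaperone BiP	24
NOS2	Nitric oxide synthase, inducible	23
CCNA2	Cyclin-A2	22
MMP3	Stromelysin-1	22
MMP1	Interstitial collagenase	21
SELE	E-selectin	21
PTPN11	Tyrosine-protein phosphatase non-receptor type 11	21
MMP7	Matrilysin	20
FYN	Tyrosine-protein kinase Fyn	20
LGALS3	Galectin-3	19
SIRT2	NAD-dependent protein deacetylase sirtuin-2	17
MMP13	Collagenase 3	17
DNMT1	DNA (cytosine-5)-methyltransferase 1	17
IGFBP3	Insulin-like growth factor-binding protein 3	17
PLAT	Tissue-type plasminogen activator	16
NOS1	Nitric oxide synthase, brain	15
SELP	P-selectin	15
HDAC4	Histone deacetylase 4	15
BCL2A1	Bcl-2-related protein A1	15
TLR9	Toll-like receptor 9	15
TOP1	DNA topoisomerase 1	14
AKR1B1	Aldo-keto reductase family 1 member B1	14
MIF	Macrophage migration inhibitory factor	13
BCL2	Apoptosis regulator Bcl-2	13
MMP8	Neutrophil collagenase	12
ADORA2A	Adenosine receptor A2a	11
RPS6KA3	Ribosomal protein S6 kinase alpha-3	11
LGALS4	Galectin-4	10
MGAM	Maltase-glucoamylase, intestinal	10
PTGS1	Prostaglandin G/H synthase 1	10
ADA	Adenosine deaminase	8
ADORA3	Adenosine receptor A3	8
SELL	L-selectin	8
MMP12	Macrophage metalloelastase	8
EDNRA	Endothelin-1 receptor	7
MGEA5	Protein O-GlcNAcase	7
P2RY2	P2Y purinoceptor 2	6
TYR	Tyrosinase	6
GLP1R	Glucagon-like peptide 1 receptor	6
NR2F2	COUP transcription factor 2	6
PSEN2	Presenilin-2	6
GBA	Lysosomal acid glucosylceramidase	6
PNP	Purine nucleoside phosphorylase	5
SLC6A3	Sodium-dependent dopamine transporter	5
PYGM	Glycogen phosphorylase, muscle form	5
PTPN2	Tyrosine-protein phosphatase non-receptor type 2	5
S1PR2	Sphingosine 1-phosphate receptor 2	5
DYRK1A	Dual specificity tyrosine-phosphorylation-regulated kinase 1A	4
CA2	Carbonic anhydrase 2	3
CYP2D6	Cytochrome P450 2D6	3
SLC5A1	Sodium/glucose cotransporter 1	3
NCSTN	Nicastrin	3
ATIC	Bifunctional purine biosynthesis protein ATIC	2
CYP1A2	Cytochrome P450 1A2	2
CA1	Carbonic anhydrase 1	2
ALOX12	Polyunsaturated fatty acid lipoxygenase ALOX12	2
ICMT	Protein-S-isoprenylcysteine O-methyltransferase	2
GAA	Lysosomal alpha-glucosidase	2
PSENEN	Gamma-secretase subunit PEN-2	2
ADH1A	Alcohol dehydrogenase 1A	1
FUCA1	Tissue alpha-L-fucosidase	1
MAG	Myelin-associated glycoprotein	1
GPR35	G-protein coupled receptor 35	1
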