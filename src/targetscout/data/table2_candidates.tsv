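gene	category	compartment	fals_value	fals_p	sals_value	sals_p	protein_family	tissue_enrichment	aging_associated	proteomic_source	mechanism
ADRA2B	high_confidence	CNS	80		50		GPCR	Low tissue specificity	0	0	Protein degradation
CYBB	high_confidence	CNS	80		86		Ion channel	Blood, lung, lymphoid tissue	0	0	Oxidative stress
FLT1	high_confidence	CNS	80		57		Receptor kinase	Placenta	1	0	Inflammation
MAP3K5	high_confidence	CNS	80		71		Protein kinase	Adrenal gland	1	0	Apoptosis
MAPK1	high_confidence	CNS	80		71		CMGC kinase	Brain	0	0	Apoptosis
NOS1	high_confidence	CNS	80		86		Oxidoreductase	Brain and skeletal muscle	0	0	Oxidative stress
NR3C1	high_confidence	CNS	80		86		Nuclear receptor	Low tissue specificity	1	0	Inflammation, excitotoxicity
PTK2	high_confidence	CNS	40		86		Tyrosine kinase	Low tissue specificity	1	0	Protein aggregation
PTPRC	high_confidence	CNS	80		86		Receptor phosphatase	Blood, lymphoid tissue	0	0	Inflammation
RARA	high_confidence	CNS	50		14		Nuclear receptor	Low tissue specificity	0	0	Neurogenesis
AHCYL1	novel	CNS	100		71		Enzyme	Low tissue specificity	0	0	Apoptosis
KCNB2	novel	CNS	60		83		Ion channel	Brain, lymphoid tissue, pituitary gland	0	0	Excitotoxicity
P2RY14	novel	CNS	40		14		GPCR	Granulocytes, dendritic cells, placenta	0	0	Inflammation
SCYL1	novel	CNS	40		14		Protein kinase	Low tissue specificity	0	0	Apoptosis
SLC25A10	novel	CNS	20		29		Transporter	Liver	0	0	Oxidative stress
STUB1	novel	CNS	20		14		Acyltransferase	Low tissue specificity	1	0	Protein degradation
DNMT3A	high_confidence	diMN	0.1324	0.0346	0.0773	0.1172	Methyltransferase	Low tissue specificity	0	0	Apoptosis
ERN1	high_confidence	diMN	0.2058	0.003	0.0699	0.1644	Protein kinase	Low tissue specificity	0	0	Protein aggregation, apoptosis
G6PD	high_confidence	diMN	-0.1416	0.0487	-0.0847	0.1337	Oxidoreductase	Testis	0	1	Oxidative stress
HSPD1	high_confidence	diMN	0.1363	0.1365	0.1916	0.0083	Isomerase	Vagina	1	1	FUS pathology, inflammation
PPIA	high_confidence	diMN	0.1728	0.0338	0.2361	0.0003	Isomerase	Low tissue specificity	1	1	TDP-43 pathology, inflammation
RPS6KB1	high_confidence	diMN	0.1558	0.0297	0.1426	0.0052	AGC kinase	Low tissue specificity	0	0	Protein aggregation
VCP	high_confidence	diMN	0.0212	0.637	0.0776	0.0411	Hydrolase	Low tissue specificity	1	1	Mitochondrial dysfunction
KCNS3	novel	diMN	0.3886	0.0995	0.3338	0.0282	Ion channel	Skeletal muscle	0	0	Excitotoxicity
PPP3CB	novel	diMN	-0.3048	0.0115	-0.1371	0.1725	Esterase	Skeletal muscle	0	1	Protein aggregate degradation
PSMC6	novel	diMN	-0.2636	0.0402	-0.1502	0.0926	Hydrolase	Low tissue specificity	0	1	Proteostasis
METTL21A	novel	diMN	0.196	0.0012	0.0827	0.0432	Methyltransferase	Low tissue specificity	0	0	Protein aggregation
TOPORS	novel	diMN	0.2161	0.0135	0.1385	0.0184	Acyltransferase	Low tissue specificity	0	0	Apoptosis
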