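subtype	series	platform	technology	source	mutant_gene	n_case	n_control	year
fALS	E-MTAB-1925	A-MEXP-2246	Microarray	Motor Cortex	C9orf72	3	3	2013
fALS	GSE67196	GPL11154	RNA-seq	Cerebellum	C9orf72	8	8	2015
fALS	GSE67196	GPL11154	RNA-seq	Frontal Cortex	C9orf72	8	9	2015
fALS	GSE68605	GPL570	Microarray	Motor Neurons	C9orf72	8	3	2015
fALS	GSE20589	GPL570	Microarray	Motor Neurons	SOD1	3	7	2010
sALS	GSE122649	GPL18573	RNA-seq	Motor Cortex	-	26	12	2018
sALS	GSE124439	GPL16791	RNA-seq	Frontal Cortex	-	65	9	2018
sALS	GSE124439	GPL16791	RNA-seq	Motor Cortex	-	80	8	2018
sALS	GSE19332	GPL570	Microarray	Motor Neurons	-	3	7	2009
sALS	GSE76220	GPL9115	RNA-seq	Spinal Motor Neurons	-	13	8	2015
sALS	GSE67196	GPL11154	RNA-seq	Cerebellum	-	10	8	2015
sALS	GSE67196	GPL11154	RNA-seq	Frontal Cortex	-	10	9	2015
fALS	Answer ALS	Novaseq 6000	RNA-seq	diMN	-	25	31	2022
sALS	Answer ALS	Novaseq 6000	RNA-seq	diMN	-	110	31	2022
fALS	Answer ALS	SCIEX 6600	SWATH-MS	diMN	-	25	31	2022
sALS	Answer ALS	SCIEX 6600	SWATH-MS	diMN	-	110	31	2022
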