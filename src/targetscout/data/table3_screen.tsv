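human_gene	fly_symbol	model_available	score	interpretation	reference
KCNB2	Shab	Yes	-3.5	Strong rescue
KCNS3	Shab	Yes	-3.5	Strong rescue
VCP	TER94	Yes	-3.5	Strong rescue	B110
ADRA2B	Octa2R	Yes	-3	Strong rescue
NR3C1	ERR	Yes	-3	Strong rescue
P2RY14	AstC-R1	Yes	-3	Strong rescue
P2RY14	AstC-R2	Yes	-2	Moderate rescue
PPP3CB	Pp2B-14D	Yes	-3	Strong rescue
PPP3CB	CanA-14F	Yes	-2	Moderate rescue
PTPRC	Ptp69D	Yes	-3	Strong rescue
RARA	Eip78C	Yes	-3	Strong rescue
RARA	EcR	Yes	-2.5	Moderate rescue
RARA	Hr96	Yes	-2	Moderate rescue
RARA	Eip75B	Yes	Lethal
PTK2	Fak	Yes	-2.5	Moderate rescue
AHCYL1	AhcyL1	Yes	-2	Moderate rescue
DNMT3A	ADD1	Yes	-2	Moderate rescue
DNMT3A	sba	Yes	0	No modification
ERN1	Ire1	Yes	-2	Moderate rescue
MAP3K5	Ask1	Yes	-2	Moderate rescue
MAPK1	rl	Yes	-2	Moderate rescue
SCYL1	yata	Yes	-2	Moderate rescue
STUB1	STUB1	Yes	-2	Moderate rescue
TOPORS	Topors	Yes	-2	Moderate rescue
G6PD	Zw	Yes	-1	Mild rescue
NOS1	Nos	Yes	-1	Mild rescue
HSPD1	Hsp60A	Yes	-0.5	No modification
CYBB	Duox	Yes	0	No modification
PSMC6	Rpt4	Yes	0	No modification	B110
PPIA	CG7768	Yes	0.5	No modification	B65
PPIA	Cyp1	Yes	0.5	No modification	B65
FLT1	Pvr	Yes	1	Mild enhancement	B65
RPS6KB1	S6k	Yes	2	Moderate enhancement
METTL21A	CG5013	No
SLC25A10	Dic1	No
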