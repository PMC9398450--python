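eec_gene	te_gene	cluster_membership	classifier_status
LOXL1	FBLN5	polar_and_mural	yes
IGF1	IGFBP7	polar_and_mural	yes
CRISPLD2	HSP90AB1	polar	yes
NOG	NOG	polar	yes
CP	LTF	polar	yes
TNC	NCAN	polar	yes
NRXN1	NLGN1	mural	yes
ALPP	COL2A1	mural	yes
SERPINB8	FURIN	mural	yes
CST7	POTEE	mural	yes
FLNB	PSEN1	mural	yes
TGFBR3	TGFB1	mural	yes
VCAN	HAPLN1	mural	yes
HEXB	HEXB	mural	yes
CSTB	CTSH	mural	yes
SLPI	PLSCR1	mural	yes
AMBP	AMBP	polar_and_mural	no
KLKB1	KNG1	mural	no
GUSB	CES1	mural	no
THBD	F2	mural	no
C4BPA	APCS	polar_and_mural	nd_not_expressed
IFNG	IFNG	polar_and_mural	nd_not_expressed
IFNAR2	IFNA2	polar_and_mural	nd_not_expressed
SERPING1	SELE	polar_and_mural	nd_not_expressed
FGA	FGB	mural	nd_not_expressed
SFRP1	FZD6	neither	nd
DKK3	UBA52	neither	nd
LAMA1	FBLN2	neither	nd
DCN	EGFR	neither	nd
F2	SERPINE1	neither	nd
CD55	CD55	neither	nd
PPFIBP2	APP	neither	nd
ANXA2	CTSB	neither	nd
PROS1	F5	neither	nd
ANK3	KCNC1	neither	nd
CPE	ROBO2	neither	nd
GPLD1	APOA4	neither	nd
FGG	FGA	neither	nd
APOD	APOD	neither	nd
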