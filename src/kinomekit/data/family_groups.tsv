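family	group
AGC_MAST	AGC
AGC_PDK1	AGC
AGC_PKA-PKG	AGC
AGC_RSK-2	AGC
Aur	Aur
BUB	BUB
CAMK_AMPK	CAMK
CAMK_CAMKL-CHK1	CAMK
CAMK_CDPK	CAMK
CK1_CK1	CK1
CMGC_CDK-CCRK	CMGC
CMGC_CDK-CDK8	CMGC
CMGC_CDK-PITSLRE	CMGC
CMGC_CDK-Pl	CMGC
CMGC_GSK	CMGC
CMGC_MAPK	CMGC
CMGC_Pl-The	CMGC
Group-Pl-4	Group-Pl
IRE1	IRE1
NAK	NAK
NEK	NEK
PEK_GCN2	PEK_GCN2
RLK-Pelle_C-LEC	RLK-Pelle
RLK-Pelle_DLSV	RLK-Pelle
RLK-Pelle_L-LEC	RLK-Pelle
RLK-Pelle_LRK10L-2	RLK-Pelle
RLK-Pelle_LRR-I-1	RLK-Pelle
RLK-Pelle_LRR-II	RLK-Pelle
RLK-Pelle_LRR-IV	RLK-Pelle
RLK-Pelle_LRR-VI-2	RLK-Pelle
RLK-Pelle_LRR-VII-2	RLK-Pelle
RLK-Pelle_LRR-VII-3	RLK-Pelle
RLK-Pelle_LRR-XI-1	RLK-Pelle
RLK-Pelle_LRR-XIIIb	RLK-Pelle
RLK-Pelle_LRR-XIV	RLK-Pelle
RLK-Pelle_LRR-XV	RLK-Pelle
RLK-Pelle_LRR-Xb-2	RLK-Pelle
RLK-Pelle_PERK-1	RLK-Pelle
RLK-Pelle_RLCK-II	RLK-Pelle
RLK-Pelle_RLCK-IV	RLK-Pelle
RLK-Pelle_RLCK-IXa	RLK-Pelle
RLK-Pelle_RLCK-IXb	RLK-Pelle
RLK-Pelle_RLCK-Os	RLK-Pelle
RLK-Pelle_RLCK-VIIa-1	RLK-Pelle
RLK-Pelle_RLCK-VIIb	RLK-Pelle
RLK-Pelle_RLCK-VIII	RLK-Pelle
RLK-Pelle_RLCK-XII-2	RLK-Pelle
RLK-Pelle_SD-1	RLK-Pelle
RLK-Pelle_WAK	RLK-Pelle
SCY1_SCY1	SCY1
STE_STE11	STE
STE_STE20	STE
STE_STE7	STE
TKL-Pl-4	TKL
TKL-Pl-6	TKL
TKL_CTR1-DRK-2	TKL
TLK	TLK
TTK	TTK
ULK_ULK4	ULK
WEE_WEE1	WEE
WNK_NRBP	WNK
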