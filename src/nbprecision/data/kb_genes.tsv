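symbol	role	predisposition_flag	pathway
ALK	oncogene	True	RTK/growth factor signaling
MYCN	oncogene	False	transcriptional regulation
ATRX	tumor_suppressor	False	chromatin remodeling/DNA damage
MDM2	oncogene	False	TP53 pathway
MDM4	oncogene	False	TP53 pathway
CDK4	oncogene	False	cell cycle control
CDK6	oncogene	False	cell cycle control
CCND1	oncogene	False	cell cycle control
CDKN2A	tumor_suppressor	False	cell cycle control
CDKN2B	tumor_suppressor	False	cell cycle control
RB1	tumor_suppressor	True	cell cycle control
WEE1	oncogene	False	cell cycle control
CHEK1	oncogene	False	DNA damage/repair
TP53	tumor_suppressor	True	DNA damage/repair
ATM	tumor_suppressor	True	DNA damage/repair
BRCA1	tumor_suppressor	True	DNA damage/repair
BRCA2	tumor_suppressor	True	DNA damage/repair
PALB2	tumor_suppressor	True	DNA damage/repair
TOP2A	oncogene	False	DNA damage/repair
PIK3CA	oncogene	False	PI3K/AKT/mTOR signaling
PTEN	tumor_suppressor	True	PI3K/AKT/mTOR signaling
MTOR	oncogene	False	PI3K/AKT/mTOR signaling
AKT1	oncogene	False	PI3K/AKT/mTOR signaling
BRAF	oncogene	False	RAS/MAPK signaling
KRAS	oncogene	False	RAS/MAPK signaling
NRAS	oncogene	False	RAS/MAPK signaling
HRAS	oncogene	False	RAS/MAPK signaling
NF1	tumor_suppressor	True	RAS/MAPK signaling
EGFR	oncogene	False	RTK/growth factor signaling
ERBB2	oncogene	False	RTK/growth factor signaling
FGFR1	oncogene	False	RTK/growth factor signaling
KIT	oncogene	False	RTK/growth factor signaling
MET	oncogene	False	RTK/growth factor signaling
RET	oncogene	True	RTK/growth factor signaling
NTRK1	oncogene	False	RTK/growth factor signaling
AURKA	oncogene	False	mitotic regulation
PHOX2B	both	True	transcriptional regulation
TERT	oncogene	False	telomere maintenance
HIF1A	oncogene	False	hypoxia response
CUL4A	oncogene	False	ubiquitin/proteasome
PSMC2	oncogene	False	ubiquitin/proteasome
TNKS	oncogene	False	WNT signaling
MITF	both	True	transcriptional regulation
TSHR	both	True	GPCR signaling
SMARCA4	tumor_suppressor	False	chromatin remodeling/DNA damage
ARID1A	tumor_suppressor	False	chromatin remodeling/DNA damage
IMMUNE_CHECKPOINT	unknown	False	immune checkpoint
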