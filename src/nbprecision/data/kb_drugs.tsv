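gene	drug	mechanism	evidence	stage
ALK	lorlatinib	inhibitor	validated_direct	investigational
ALK	crizotinib	inhibitor	validated_direct	approved
MYCN	BET-bromodomain inhibitor	other	validated_direct	investigational
ATRX	olaparib+irinotecan	other	validated_direct	investigational
MDM2	idasanutlin	antagonist	validated_direct	investigational
MDM4	ALRN-6924	antagonist	pathway_predicted	investigational
CDK4	palbociclib	inhibitor	validated_direct	approved
CDK6	ribociclib	inhibitor	validated_direct	approved
CCND1	abemaciclib	other	validated_direct	approved
CDKN2A	palbociclib (CDK4/6 pathway)	other	validated_direct	approved
CDKN2B	ribociclib (CDK4/6 pathway)	other	validated_direct	approved
RB1	CDK-independent combination	other	pathway_predicted	investigational
WEE1	adavosertib	inhibitor	validated_direct	investigational
CHEK1	prexasertib	inhibitor	validated_direct	investigational
TP53	APR-246	other	pathway_predicted	investigational
ATM	olaparib (synthetic lethal)	other	pathway_predicted	investigational
BRCA1	olaparib	other	validated_direct	approved
BRCA2	talazoparib	other	validated_direct	approved
PALB2	olaparib (HRD pathway)	other	pathway_predicted	investigational
TOP2A	doxorubicin	inhibitor	validated_direct	approved
PIK3CA	alpelisib	inhibitor	validated_direct	approved
PTEN	AKT-inhibitor combination	other	pathway_predicted	investigational
MTOR	everolimus	inhibitor	validated_direct	approved
AKT1	capivasertib	inhibitor	validated_direct	investigational
BRAF	dabrafenib	inhibitor	validated_direct	approved
KRAS	sotorasib	inhibitor	validated_direct	approved
NRAS	trametinib (MEK pathway)	inhibitor	pathway_predicted	approved
HRAS	tipifarnib	inhibitor	validated_direct	investigational
NF1	selumetinib (MEK pathway)	other	pathway_predicted	approved
EGFR	erlotinib	inhibitor	validated_direct	approved
ERBB2	trastuzumab	antagonist	validated_direct	approved
FGFR1	erdafitinib	inhibitor	validated_direct	approved
KIT	imatinib	inhibitor	validated_direct	approved
MET	capmatinib	inhibitor	validated_direct	approved
RET	selpercatinib	inhibitor	validated_direct	approved
NTRK1	larotrectinib	inhibitor	validated_direct	approved
AURKA	alisertib	inhibitor	validated_direct	investigational
PHOX2B	ALK-pathway combination	other	pathway_predicted	investigational
TERT	imetelstat	inhibitor	pathway_predicted	investigational
HIF1A	belzutifan	inhibitor	validated_direct	approved
CUL4A	pevonedistat	inhibitor	pathway_predicted	investigational
PSMC2	carfilzomib	inhibitor	pathway_predicted	approved
TNKS	tankyrase inhibitor G007-LK	inhibitor	pathway_predicted	investigational
MITF	HDAC-inhibitor combination	other	pathway_predicted	investigational
TSHR	TSHR-antagonist	antagonist	pathway_predicted	investigational
SMARCA4	EZH2-inhibitor (tazemetostat)	other	pathway_predicted	approved
ARID1A	EZH2-inhibitor (tazemetostat)	other	pathway_predicted	approved
IMMUNE_CHECKPOINT	pembrolizumab	antagonist	validated_direct	approved
IMMUNE_CHECKPOINT	nivolumab	antagonist	validated_direct	approved
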