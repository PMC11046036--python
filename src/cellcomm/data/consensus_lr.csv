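ligand,receptor
TGFB1,TGFBR1_TGFBR2
TGFB2,TGFBR1_TGFBR2
TGFB3,TGFBR1_TGFBR2
IL6,IL6R_IL6ST
IL10,IL10RA_IL10RB
IL1B,IL1R1_IL1RAP
IL15,IL15RA_IL2RB_IL2RG
IL2,IL2RA_IL2RB_IL2RG
IL4,IL4R_IL2RG
IL7,IL7R_IL2RG
TNF,TNFRSF1A
TNF,TNFRSF1B
LTA,TNFRSF14
TNFSF10,TNFRSF10A
TNFSF10,TNFRSF10B
TNFSF13B,TNFRSF13B
CD40LG,CD40
FASLG,FAS
CXCL12,CXCR4
CXCL12,ACKR3
CXCL9,CXCR3
CXCL10,CXCR3
CXCL11,CXCR3
CXCL8,CXCR1
CXCL8,CXCR2
CCL2,CCR2
CCL3,CCR1
CCL3,CCR5
CCL4,CCR5
CCL5,CCR1
CCL5,CCR5
CCL19,CCR7
CCL21,CCR7
CCL20,CCR6
CX3CL1,CX3CR1
CSF1,CSF1R
CSF2,CSF2RA_CSF2RB
IFNG,IFNGR1_IFNGR2
IFNB1,IFNAR1_IFNAR2
IFNA1,IFNAR1_IFNAR2
EGF,EGFR
TGFA,EGFR
HBEGF,EGFR
AREG,EGFR
NRG1,ERBB3
NRG1,ERBB4
VEGFA,FLT1
VEGFA,KDR
VEGFB,FLT1
VEGFC,FLT4
PGF,FLT1
FGF2,FGFR1
FGF7,FGFR2
FGF1,FGFR1
HGF,MET
IGF1,IGF1R
IGF2,IGF1R
INS,INSR
PDGFA,PDGFRA
PDGFB,PDGFRB
PDGFC,PDGFRA
ANGPT1,TEK
ANGPT2,TEK
DLL1,NOTCH1
DLL4,NOTCH1
JAG1,NOTCH1
JAG1,NOTCH2
JAG2,NOTCH1
WNT3A,FZD1_LRP6
WNT5A,FZD2
WNT5A,ROR2
SHH,PTCH1
DHH,PTCH1
BMP2,BMPR1A_BMPR2
BMP4,BMPR1A_BMPR2
BMP7,BMPR1B_BMPR2
GDF15,RET_GFRAL
NODAL,ACVR1B_ACVR2A
INHBA,ACVR1B_ACVR2B
EFNA1,EPHA2
EFNB1,EPHB2
EFNB2,EPHB4
SEMA3A,NRP1_PLXNA1
SEMA4D,PLXNB1
SLIT2,ROBO1
NTN1,DCC
BDNF,NTRK2
NGF,NTRK1
ICAM1,ITGAL_ITGB2
VCAM1,ITGA4_ITGB1
FN1,ITGA5_ITGB1
COL1A1,ITGA1_ITGB1
COL1A1,ITGA2_ITGB1
LAMB1,ITGA6_ITGB1
THBS1,CD47
THBS1,CD36
SPP1,ITGAV_ITGB3
SPP1,CD44
VIM,CD44
HAS2,CD44
MIF,CD74_CXCR4
MIF,CD74_CD44
APP,CD74
GRN,SORT1
LGALS9,HAVCR2
PVR,TIGIT
CD274,PDCD1
PDCD1LG2,PDCD1
CD80,CTLA4
CD86,CD28
HLA-A,KIR3DL1
HLA-E,KLRC1_KLRD1
ANXA1,FPR1
ANXA1,FPR2
RETN,CAP1
PROS1,AXL
GAS6,AXL
GAS6,MERTK
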