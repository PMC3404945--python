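AMYG_L
AMYG_R
ANG_L
ANG_R
CALC_L
CALC_R
CN_L
CN_R
ACC_L
ACC_R
MCC_L
MCC_R
PCC_L
PCC_R
CUN_L
CUN_R
IFOp_L
IFOp_R
IFOr_L
IFOr_R
IFTr_L
IFTr_R
MedFOr_L
MedFOr_R
MFG_L
MFG_R
MFOr_L
MFOr_R
SFG_L
SFG_R
MedSF_L
MedSF_R
SFOr_L
SFOr_R
FG_L
FG_R
HSHL_L
HSHL_R
HIPP_L
HIPP_R
INS_L
INS_R
LNG_L
LNG_R
IOG_L
IOG_R
MOG_L
MOG_R
SOG_L
SOG_R
OFB_L
OFB_R
PLD_L
PLD_R
PCL_L
PCL_R
PHIP_L
PHIP_R
IPL_L
IPL_R
SPL_L
SPL_R
PoCG_L
PoCG_R
PrCG_L
PrCG_R
PCUN_L
PCUN_R
PUT_L
PUT_R
REC_L
REC_R
RLN_L
RLN_R
SMA_L
SMA_R
SMG_L
SMG_R
ITG_L
ITG_R
MTG_L
MTG_R
MTP_L
MTP_R
STP_L
STP_R
STG_L
STG_R
THL_L
THL_R
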