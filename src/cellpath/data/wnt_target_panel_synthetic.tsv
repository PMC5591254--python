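gene	p_up_given_active	p_up_given_inactive	p_high_given_up	p_high_given_down
AXIN2				
ASCL2				
LGR5				
SP5				
NKD1				
CCND1				
MYC				
TCF7				
LEF1				
BMP4				
CD44				
MET				
EPHB2				
EPHB3				
SOX9				
JAG1				
DKK1				
NOTUM				
RNF43				
ZNRF3				
TNFRSF19				
PROX1				
EDN1				
FGF20				
FOSL1				
ID2				
L1CAM				
MMP7				
PLAUR				
PPARD				
TIAM1				
VEGFA				
WISP1				
BIRC5				
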