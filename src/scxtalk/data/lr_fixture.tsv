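ligand	receptor	source
PLAU	PLAUR	literature
IL1B	IL1R1	literature
IL6	IL6ST	literature
PLA2G2A	ITGB1	literature
HAS2	CD44	literature
IGF2	INSR	literature
LPL	VLDLR	literature
APOE	LDLR	literature
COL1A1	ITGA5	literature
COL1A2	ITGA11	literature
FN1	ITGA5	literature
FBN1	ITGB1	literature
FBLN1	ITGB1	literature
COL1A1	ITGA11	literature
VCAN	ITGB1	literature
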