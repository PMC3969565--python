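target	target_net	modifier	modifier_net	ptm	target_age	modifier_age
ATM	CHK	ATM	CHK	P	V	V
ATM	CHK	KAT5	GNR|DSB	A	V	E
BRCA1	GR	ATM	CHK	P	E	V
BRCA1	GR	ATR	CHK	P	E	E
BRCA1	GR	CHEK2	CHK	P	E	U
BRCA1	GR	PIAS1	DSB	S	E	V
BRCA1	GR	UBE2T	DSB	U	E	Pr
BRCA2	GR	CHEK1	CHK	P	E	O
BRCA2	GR	CHEK2	CHK	P	E	U
BRCA2	GR	ATM	CHK	P	E	V
BRCA2	GR	ATR	CHK	P	E	E
CDT1	CHK	CUL4	GNR|CHK	U	E	E
CHEK1	CHK	ATR	CHK	P	O	E
CHEK2	CHK	ATM	CHK	P	E	V
CLSPN	CHK	CHEK1	CHK	P	O	O
CLSPN	CHK	ATR	CHK	P	O	E
CLSPN	CHK	PLK1	CHK	P	O	Pr
CLSPN	CHK	CUL1	CHK	U	O	E
CLSPN	CHK	RBX1	CHK	U	O	E
DCLRE1B	GR	ATR	CHK	P	E	E
DCLRE1B	GR	ATM	CHK	P	E	V
DCR1C	GR	ATM	CHK	P	E	V
DCR1C	GR	PRKDC	CHK	P	E	E
EXO1	GR	ATR	CHK	P	E	E
FAM175A	DSB	ATM	CHK	P	Vr	V
FAM175A	DSB	ATR	CHK	P	Vr	E
FANCD2	GR	ATM	CHK	P	E	V
FANCL	GR	UBE2T	GR	U	E	Pr
FBX031	CHK	ATM	CHK	P	M	V
H2AFX	DSB	PRKDC	CHK	P	E	E
H2AFX	DSB	ATM	CHK	P	E	V
H2AFX	DSB	UBE2N	CHK	U	E	Pr
H2AFX	DSB	RNF168	DSB	U	E	Ch
H2AFX	DSB	RNF8	DSB	U	E	E
H2AFX	DSB	KAT5	GNR|DSB	A	E	E
HERC2	DSB	ATM	DSB	P	M	V
HNRPK	CHK	MDM2	CHK	U	O	M
MDM2	CHK	ATM	CHK	P	M	V
MDM4	CHK	CHEK1	CHK	P	Vr	O
MDM4	CHK	CHEK2	CHK	P	Vr	U
MDM4	CHK	ATM	CHK	P	Vr	V
MAPK3	CHK	MAPKAPK2	CHK	P	E	O
Cdc25A	CHK	CHEK1	CHK	P	U	O
Cdc25A	CHK	CHEK2	CHK	P	U	U
Cdc25C	CHK	CHEK1	CHK	P	O	O
Cdc25C	CHK	CHEK2	CHK	P	O	U
Cdc25C	CHK	MAPKAPK2	CHK	P	O	O
MSH2	GR	ATM	CHK	P	E	V
MSH2	GR	ATR	CHK	P	E	E
MSH3	GR	ATM	CHK	P	Pr	V
MSH3	GR	ATR	CHK	P	Pr	E
MSH6	GR	ATR	CHK	P	Pr	E
KAT8	GR	KAT8	GR	A	E	E
NBN	GR|DSB	ATM	CHK	P	V	V
NR4A2	RFN|GR	PRKDC	CHK	P	B	E
PALB2	GR	ATM	CHK	P	Vr	V
PALB2	GR	ATR	CHK	P	Vr	E
PRKDC	GR	PRKDC	CHK	P	E	E
RAD17	RFN	ATM	CHK	P	E	V
RAD17	RFN	ATR	CHK	P	E	E
RAD50	GR|DSB	ATM	CHK	P	Pr	V
RAD50	GR|DSB	ATR	CHK	P	Pr	E
RAD51	GR|DSB	CHEK1	CHK	P	Pr	O
RAD9A	CHK	ATM	CHK	P	E	V
RAD9A	CHK	ATR	CHK	P	E	E
RBBP8	GR	ATM	CHK	P	B	V
RBBP8	GR	BRCA1	GR	U	B	E
RPA1	RFN	ATM	CHK	P	E	V
RPA1	RFN	ATR	CHK	P	E	E
RPA2	RFN	PRKDC	CHK	P	E	E
RNF168	DSB	PIAS4	DSB	S	Ch	Vr
RNF8	DSB	PIAS4	DSB	S	E	Vr
SMC1A	DSB	ATM	CHK	P	Pr	V
SMC1A	DSB	ATR	CHK	P	Pr	E
SMC5	GR	NSMCE2	GR	S	E	E
SMC6	GR	NSMCE2	GR	S	E	E
TRIM28	CHK	ATM	CHK	P	B	V
TRIM28	CHK	CHEK2	CHK	P	B	U
TRIM28	CHK	CHEK1	CHK	P	B	O
TRIM28	CHK	TRIM28	CHK	S	B	B
TIPIN	RFN	ATR	CHK	P	V	E
TIPIN	RFN	ATM	CHK	P	V	V
TOPB1	CHK	UBR5	RFN	U	E	M
TRIP12	DSB	ATM	CHK	P	E	V
TRIP12	DSB	ATR	CHK	P	E	E
UBE2T	GR	UBE2T	GR	U	Pr	Pr
UIMC1	DSB	ATM	CHK	P	Vr	V
UIMC1	DSB	ATR	CHK	P	Vr	E
UIMC1	DSB	PIAS1	DSB	S	Vr	V
WEE1	CHK	PLK1	DSB	P	E	Pr
WEE1	CHK	CUL1	DSB	U	E	E
WEE1	CHK	RBX1	CHK	U	E	E
XPA	GR	ATM	CHK	P	E	V
XPA	GR	ATR	CHK	P	E	E
XPA	GR	SIRT1	GR	deA	E	U
XRCC1	GR	PRKDC	GR	P	E	E
XRCC4	GR	PRKDC	GR	P	V	E
XRCC5	GR	PRKDC	GR	P	E	E
XRCC6	GR	PRKDC	GR	P	E	E
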