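gene	moi	chromosome	category	panel_version
PAX2	AD	10	CAKUT	demo-1
HNF1B	AD	17	CAKUT	demo-1
EYA1	AD	8	CAKUT	demo-1
GATA3	AD	10	CAKUT	demo-1
SALL1	AD	16	CAKUT	demo-1
FRAS1	AR	4	CAKUT	demo-1
ROBO2	AD	3	CAKUT	demo-1
PKD1	AD	16	ciliopathy	demo-1
PKD2	AD	4	ciliopathy	demo-1
PKHD1	AR	6	ciliopathy	demo-1
NPHP1	AR	2	ciliopathy	demo-1
CEP290	AR	12	ciliopathy	demo-1
TMEM67	AR	8	ciliopathy	demo-1
BBS1	AR	11	ciliopathy	demo-1
IFT140	AR	16	ciliopathy	demo-1
NPHP4	AR	1	ciliopathy	demo-1
COL4A5	XLD	X	glomerulopathy	demo-1
COL4A3	AR	2	glomerulopathy	demo-1
COL4A4	AR	2	glomerulopathy	demo-1
NPHS1	AR	19	glomerulopathy	demo-1
NPHS2	AR	1	glomerulopathy	demo-1
WT1	AD	11	glomerulopathy	demo-1
TRPC6	AD	11	glomerulopathy	demo-1
CFH	AD	1	glomerulopathy	demo-1
LMX1B	AD	9	glomerulopathy	demo-1
INF2	AD	14	glomerulopathy	demo-1
PTPRO	AR	12	glomerulopathy	demo-1
AGXT	AR	2	nephrolithiasis	demo-1
SLC3A1	AR	2	nephrolithiasis	demo-1
SLC7A9	AR	19	nephrolithiasis	demo-1
CYP24A1	AR	20	nephrolithiasis	demo-1
SLC34A1	AR	5	nephrolithiasis	demo-1
ADCY10	AD	1	nephrolithiasis	demo-1
CLDN19	AR	1	nephrolithiasis	demo-1
SLC12A3	AR	16	tubulopathy	demo-1
CLCNKB	AR	1	tubulopathy	demo-1
CLDN16	AR	3	tubulopathy	demo-1
OCRL	XLR	X	tubulopathy	demo-1
UMOD	AD	16	tubulopathy	demo-1
BSND	AR	1	tubulopathy	demo-1
TSC2	AD	16	other	demo-1
TSC1	AD	9	other	demo-1
WDR19	AR	4	other	demo-1
ZEB2	AD	2	other	demo-1
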