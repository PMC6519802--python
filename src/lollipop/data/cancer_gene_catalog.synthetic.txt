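# Synthetic stand-in oncogene / tumor-suppressor catalog (409 symbols)
ABL1
ABL2
ACVR1
ACVR1B
ACVR2A
AKAP9
AKT1
AKT2
AKT3
ALK
AMER1
APC
APOBEC3B
AR
ARAF
ARHGAP26
ARID1A
ARID1B
ARID2
ARID5B
ASXL1
ASXL2
ATF1
ATIC
ATM
ATR
ATRX
AURKA
AURKB
AXIN1
AXIN2
AXL
B2M
BAP1
BARD1
BCL10
BCL11A
BCL11B
BCL2
BCL2L1
BCL2L11
BCL3
BCL6
BCL7A
BCL9
BCOR
BCORL1
BCR
BIRC3
BIRC6
BLM
BMP5
BMPR1A
BRAF
BRCA1
BRCA2
BRD4
BRIP1
BTG1
BTG2
BTK
BUB1B
CACNA1D
CALR
CAMTA1
CANT1
CARD11
CARS1
CASP8
CBFA2T3
CBFB
CBL
CBLB
CCNB1IP1
CCND1
CCND2
CCND3
CCNE1
CD274
CD74
CD79A
CD79B
CDC73
CDH1
CDK12
CDK4
CDK6
CDKN1A
CDKN1B
CDKN2A
CDKN2B
CDKN2C
CDX2
CEBPA
CHEK1
CHEK2
CHIC2
CIC
CLTC
CLTCL1
CNOT3
CREBBP
CRKL
CRLF2
CSF1R
CSF3R
CTCF
CTNNA1
CTNNB1
CUL3
CXCR4
CYLD
DAXX
DDR2
DDX3X
DICER1
DIS3
DNMT1
DNMT3A
DNMT3B
DOT1L
E2F3
EED
EGFR
EIF1AX
ELF3
EP300
EPCAM
EPHA2
EPHA3
EPHB1
ERBB2
ERBB3
ERBB4
ERCC2
ERCC3
ERCC4
ERCC5
ERG
ESR1
ETV1
ETV4
ETV5
ETV6
EWSR1
EZH2
FANCA
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCL
FAS
FAT1
FBXW7
FGF19
FGF3
FGF4
FGFR1
FGFR2
FGFR3
FGFR4
FH
FLCN
FLT1
FLT3
FLT4
FOXA1
FOXL2
FOXO1
FOXP1
FUBP1
FYN
GATA1
GATA2
GATA3
GLI1
GNA11
GNA13
GNAQ
GNAS
GRIN2A
GSK3B
H3-3A
H3-3B
HGF
HIF1A
HIST1H3B
HNF1A
HRAS
ID3
IDH1
IDH2
IGF1R
IGF2
IKBKE
IKZF1
IL7R
INHBA
INPP4B
IRF4
IRS2
JAK1
JAK2
JAK3
JUN
KDM5A
KDM5C
KDM6A
KDR
KEAP1
KEL
KIT
KLF4
KMT2A
KMT2B
KMT2C
KMT2D
KRAS
LATS1
LATS2
LMO1
LRP1B
LYN
LZTR1
MAP2K1
MAP2K2
MAP2K4
MAP3K1
MAP3K13
MAPK1
MAPK3
MAX
MCL1
MDM2
MDM4
MED12
MEF2B
MEN1
MET
MGA
MITF
MLH1
MLH3
MPL
MRE11
MSH2
MSH3
MSH6
MTOR
MUTYH
MYC
MYCL
MYCN
MYD88
MYH11
NBN
NCOR1
NCOR2
NF1
NF2
NFE2L2
NFKBIA
NKX2-1
NOTCH1
NOTCH2
NOTCH3
NOTCH4
NPM1
NRAS
NSD1
NSD2
NSD3
NT5C2
NTRK1
NTRK2
NTRK3
NUP93
PALB2
PAX3
PAX5
PAX8
PBRM1
PDCD1
PDCD1LG2
PDGFRA
PDGFRB
PHF6
PIK3C2B
PIK3CA
PIK3CB
PIK3CD
PIK3R1
PIK3R2
PIM1
PLCG2
PMS1
PMS2
POLD1
POLE
POT1
PPARG
PPM1D
PPP2R1A
PPP6C
PRDM1
PRKAR1A
PRKCI
PTCH1
PTEN
PTPN11
PTPRD
PTPRT
RAC1
RAD21
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAD52
RAD54L
RAF1
RARA
RASA1
RB1
RBM10
RECQL4
REL
RET
RHEB
RHOA
RICTOR
RIT1
RNF43
ROS1
RPS6KB1
RPTOR
RUNX1
RUNX1T1
SDHA
SDHAF2
SDHB
SDHC
SDHD
SETBP1
SETD2
SF3B1
SGK1
SH2B3
SHH
SMAD2
SMAD3
SMAD4
SMARCA4
SMARCB1
SMC1A
SMC3
SMO
SOCS1
SOX2
SOX9
SPEN
SPOP
SRC
SRSF2
STAG2
STAT3
STAT5B
STK11
SUFU
SUZ12
SYK
TAL1
TBX3
TCF3
TCF7L2
TERT
TET1
TET2
TGFBR1
TGFBR2
TNFAIP3
TNFRSF14
TOP1
TP53
TP63
TPMT
TRAF7
TSC1
TSC2
TSHR
U2AF1
USP8
VEGFA
VHL
WRN
WT1
WWTR1
XPA
XPC
XPO1
YAP1
YES1
ZFHX3
ZNF217
ZNF703
ZRSR2
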