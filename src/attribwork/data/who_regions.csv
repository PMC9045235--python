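iso3,region
AGO,AFR
BEN,AFR
BWA,AFR
BFA,AFR
BDI,AFR
CPV,AFR
CMR,AFR
CAF,AFR
TCD,AFR
COM,AFR
COG,AFR
COD,AFR
CIV,AFR
DZA,AFR
GNQ,AFR
ERI,AFR
SWZ,AFR
ETH,AFR
GAB,AFR
GMB,AFR
GHA,AFR
GIN,AFR
GNB,AFR
KEN,AFR
LSO,AFR
LBR,AFR
MDG,AFR
MWI,AFR
MLI,AFR
MRT,AFR
MUS,AFR
MOZ,AFR
NAM,AFR
NER,AFR
NGA,AFR
RWA,AFR
STP,AFR
SEN,AFR
SYC,AFR
SLE,AFR
ZAF,AFR
SSD,AFR
TGO,AFR
UGA,AFR
TZA,AFR
ZMB,AFR
ZWE,AFR
ATG,AMR
ARG,AMR
BHS,AMR
BRB,AMR
BLZ,AMR
BOL,AMR
BRA,AMR
CAN,AMR
CHL,AMR
COL,AMR
CRI,AMR
CUB,AMR
DMA,AMR
DOM,AMR
ECU,AMR
SLV,AMR
GRD,AMR
GTM,AMR
GUY,AMR
HTI,AMR
HND,AMR
JAM,AMR
MEX,AMR
NIC,AMR
PAN,AMR
PRY,AMR
PER,AMR
KNA,AMR
LCA,AMR
VCT,AMR
SUR,AMR
TTO,AMR
USA,AMR
URY,AMR
VEN,AMR
BGD,SEA
BTN,SEA
PRK,SEA
IND,SEA
IDN,SEA
MDV,SEA
MMR,SEA
NPL,SEA
LKA,SEA
THA,SEA
TLS,SEA
ALB,EUR
AND,EUR
ARM,EUR
AUT,EUR
AZE,EUR
BLR,EUR
BEL,EUR
BIH,EUR
BGR,EUR
HRV,EUR
CYP,EUR
CZE,EUR
DNK,EUR
EST,EUR
FIN,EUR
FRA,EUR
GEO,EUR
DEU,EUR
GRC,EUR
HUN,EUR
ISL,EUR
IRL,EUR
ISR,EUR
ITA,EUR
KAZ,EUR
KGZ,EUR
LVA,EUR
LTU,EUR
LUX,EUR
MLT,EUR
MCO,EUR
MNE,EUR
NLD,EUR
MKD,EUR
NOR,EUR
POL,EUR
PRT,EUR
MDA,EUR
ROU,EUR
RUS,EUR
SMR,EUR
SRB,EUR
SVK,EUR
SVN,EUR
ESP,EUR
SWE,EUR
CHE,EUR
TJK,EUR
TUR,EUR
TKM,EUR
UKR,EUR
GBR,EUR
UZB,EUR
AFG,EMR
BHR,EMR
DJI,EMR
EGY,EMR
IRN,EMR
IRQ,EMR
JOR,EMR
KWT,EMR
LBN,EMR
LBY,EMR
MAR,EMR
OMN,EMR
PAK,EMR
QAT,EMR
SAU,EMR
SOM,EMR
SDN,EMR
SYR,EMR
TUN,EMR
ARE,EMR
YEM,EMR
AUS,WPR
BRN,WPR
KHM,WPR
CHN,WPR
COK,WPR
FJI,WPR
JPN,WPR
KIR,WPR
LAO,WPR
MYS,WPR
MHL,WPR
FSM,WPR
MNG,WPR
NRU,WPR
NZL,WPR
NIU,WPR
PLW,WPR
PNG,WPR
PHL,WPR
KOR,WPR
WSM,WPR
SGP,WPR
SLB,WPR
TON,WPR
TUV,WPR
VUT,WPR
VNM,WPR
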