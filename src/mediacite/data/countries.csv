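code,continent
US,Americas
CN,Asia
GB,Europe
CA,Americas
FR,Europe
HK,Asia
AU,Oceania
DE,Europe
JP,Asia
KR,Asia
IN,Asia
ES,Europe
IT,Europe
SG,Asia
KW,Asia
EG,Africa
JO,Asia
SA,Asia
AE,Asia
ZA,Africa
NZ,Oceania
IE,Europe
NL,Europe
BE,Europe
CH,Europe
AT,Europe
SE,Europe
NO,Europe
DK,Europe
FI,Europe
PT,Europe
GR,Europe
PL,Europe
CZ,Europe
HU,Europe
RO,Europe
BG,Europe
RU,Europe
UA,Europe
TR,Asia
IL,Asia
IR,Asia
IQ,Asia
LB,Asia
QA,Asia
BH,Asia
OM,Asia
YE,Asia
PK,Asia
BD,Asia
LK,Asia
NP,Asia
TH,Asia
VN,Asia
MY,Asia
ID,Asia
PH,Asia
MM,Asia
KH,Asia
LA,Asia
TW,Asia
MO,Asia
MN,Asia
KZ,Asia
MX,Americas
BR,Americas
AR,Americas
CL,Americas
CO,Americas
PE,Americas
VE,Americas
EC,Americas
UY,Americas
BO,Americas
PY,Americas
CU,Americas
JM,Americas
TT,Americas
PA,Americas
CR,Americas
GT,Americas
NG,Africa
KE,Africa
GH,Africa
ET,Africa
TZ,Africa
UG,Africa
ZW,Africa
ZM,Africa
MA,Africa
DZ,Africa
TN,Africa
LY,Africa
SD,Africa
SN,Africa
CI,Africa
CM,Africa
CD,Africa
AO,Africa
MZ,Africa
FJ,Oceania
PG,Oceania
WS,Oceania
TO,Oceania
VU,Oceania
SB,Oceania
IS,Europe
LU,Europe
MT,Europe
CY,Europe
EE,Europe
LV,Europe
LT,Europe
SK,Europe
SI,Europe
HR,Europe
RS,Europe
BA,Europe
MK,Europe
AL,Europe
GE,Asia
AM,Asia
AZ,Asia
UZ,Asia
AF,Asia
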