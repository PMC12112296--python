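country_code,region
US,Americas
CA,Americas
BR,Americas
MX,Americas
AR,Americas
CO,Americas
CL,Americas
PE,Americas
GB,Europe
FR,Europe
DE,Europe
IT,Europe
ES,Europe
NL,Europe
BE,Europe
SE,Europe
DK,Europe
NO,Europe
FI,Europe
PL,Europe
PT,Europe
AT,Europe
CH,Europe
IE,Europe
GR,Europe
CZ,Europe
HU,Europe
RO,Europe
RU,Europe
UA,Europe
JP,Asia
CN,Asia
KR,Asia
IN,Asia
TW,Asia
TH,Asia
SG,Asia
MY,Asia
ID,Asia
PH,Asia
VN,Asia
IL,Asia
SA,Asia
TR,Asia
AU,Oceania
NZ,Oceania
ZA,Africa
EG,Africa
NG,Africa
KE,Africa
MA,Africa
TN,Africa
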