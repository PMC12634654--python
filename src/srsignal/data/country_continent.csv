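country,continent
US,Americas
USA,Americas
UNITED STATES,Americas
CA,Americas
CANADA,Americas
MX,Americas
BR,Americas
BRAZIL,Americas
AR,Americas
CL,Americas
CO,Americas
PE,Americas
JP,Asia
JAPAN,Asia
CN,Asia
CHINA,Asia
KR,Asia
KOREA,Asia
IN,Asia
INDIA,Asia
TH,Asia
VN,Asia
PH,Asia
ID,Asia
MY,Asia
SG,Asia
TW,Asia
HK,Asia
IL,Asia
SA,Asia
TR,Asia
GB,Europe
UNITED KINGDOM,Europe
FR,Europe
FRANCE,Europe
DE,Europe
GERMANY,Europe
IT,Europe
ITALY,Europe
ES,Europe
PT,Europe
NL,Europe
BE,Europe
CH,Europe
AT,Europe
SE,Europe
NO,Europe
DK,Europe
FI,Europe
PL,Europe
CZ,Europe
GR,Europe
IE,Europe
RU,Europe
UA,Europe
AU,Oceania
AUSTRALIA,Oceania
NZ,Oceania
ZA,Africa
NG,Africa
EG,Africa
KE,Africa
MA,Africa
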