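code,group
US,United States
JP,Japan
DE,Europe
FR,Europe
GB,Europe
IT,Europe
ES,Europe
NL,Europe
SE,Europe
NO,Europe
DK,Europe
FI,Europe
CH,Europe
AT,Europe
BE,Europe
PL,Europe
PT,Europe
IE,Europe
GR,Europe
CZ,Europe
HU,Europe
RO,Europe
BR,South America
AR,South America
CL,South America
CO,South America
PE,South America
VE,South America
EC,South America
UY,South America
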