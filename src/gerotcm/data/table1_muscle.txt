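MYH1
CYP2B6
MYH15
CYTL1
SLC22A7
KYNU
HOXA13
LYPD2
ACSM1
FBP2
MIOX
KRT15
COL1A1
SLC7A2
HBD
GABRP
MT-ATP8
APOD
MOBP
KDM5D
LBP
CFD
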