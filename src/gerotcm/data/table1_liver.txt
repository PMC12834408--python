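APOA1
CYP2C19
CPS1
ANKRD1
SLC34A1
CYP3A7
CD1A
CMPK2
ACSM1
DHRS2
MIOX
ABCB11
TKTL1
UGT3A2
FABP1
KRT15
SERPINA3
SRPX
CRP
SCD
TIMP4
C3
AHSG
NNMT
MT-ND4L
OVCH1
FMO3
SLC46A1
CFI
DDIT4
LBP
PIGR
LEP
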