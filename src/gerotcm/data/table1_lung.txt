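PLEKHG1
LRP1B
SLC17A7
FAM107A
SHISA2
ABCB1
MLPH
SLC5A9
ACSM1
SGMS2
PTPRG
SLC13A3
SCD
SERPINA3
SRPX
C3
SLC7A2
C4BPB
MT-CO1
B3GALT1
NNMT
OVCH1
TNR
MOBP
PZP
LRRC32
CFD
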