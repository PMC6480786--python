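# 52-gene tumour hypoxia metagene (Buffa-style signature; reconstructed
# membership, includes the canonical HIF-1A targets CA9, VEGFA and LDHA)
ACOT7
ADM
ALDOA
ANGPTL4
ANLN
BNIP3
CA9
CDKN3
CHCHD2
CORO1C
COL4A6
CTSL
DCBLD1
DDIT4
ENO1
ESRP1
GAPDH
GPI
HILPDA
HK2
KIF20A
KIF4A
LDHA
LRRC42
MAD2L2
MCTS1
MIF
MRGBP
MRPL13
MRPL15
MRPS17
NDRG1
P4HA1
PFKP
PGAM1
PGK1
PGM1
PSMA7
PSRC1
PYGB
SDC1
SEC61G
SHCBP1
SLC16A1
SLC25A32
SLC2A1
TPI1
TUBA1B
TUBB6
UTP11
VEGFA
YKT6
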