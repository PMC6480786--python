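# 32 core circadian clock genes (KEGG circadian rhythm panel, hsa04710)
ARNTL
ARNTL2
BHLHE40
BHLHE41
BTRC
CLOCK
CREB1
CRY1
CRY2
CSNK1D
CSNK1E
CUL1
FBXL3
FBXW11
NPAS2
NR1D1
NR1D2
PER1
PER2
PER3
PRKAA1
PRKAA2
PRKAB1
PRKAB2
PRKAG1
PRKAG2
PRKAG3
RBX1
RORA
RORB
RORC
SKP1
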