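# Synthetic stand-in for an external 30-gene glycolysis extension list
# (the original curated list is not public). 28 additional glycolysis /
# glucose-handling genes plus 2 genes (ENO1, PGK1) overlapping the base
# 24-gene panel, so merging yields 24 + 30 - 2 = 52 genes.
HK1
HKDC1
PFKM
PFKP
PFKFB1
PFKFB2
PFKFB3
PFKFB4
PGAM1
PGAM4
PKM
LDHC
LDHAL6A
LDHAL6B
SLC2A2
SLC2A3
SLC2A4
SLC2A5
SLC16A1
SLC16A3
MPC1
MPC2
PDHA1
PDHB
PDK1
PDK2
DLAT
DLD
ENO1
PGK1
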