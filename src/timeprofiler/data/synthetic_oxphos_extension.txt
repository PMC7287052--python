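# Synthetic stand-in for an external 112-gene OXPHOS extension list
# (the original curated list is not public). 85 additional respiratory-chain
# and assembly-factor genes plus 27 genes overlapping the base 31-gene
# panel, so merging yields 31 + 112 - 27 = 116 genes.
NDUFA3
NDUFA4
NDUFA6
NDUFA7
NDUFA9
NDUFA10
NDUFA11
NDUFA12
NDUFA13
NDUFAB1
NDUFB1
NDUFB3
NDUFB4
NDUFB6
NDUFB7
NDUFB9
NDUFB10
NDUFB11
NDUFS1
NDUFS2
NDUFS4
NDUFS5
NDUFS7
NDUFS8
NDUFV2
NDUFV3
NDUFC1
SDHB
SDHD
SDHAF1
SDHAF2
UQCRB
UQCRC2
UQCRQ
UQCRFS1
UQCR10
UQCR11
CYC1
UQCC1
UQCC2
COX4I2
COX5A
COX6A1
COX6A2
COX6B2
COX6C
COX7A2L
COX7B
COX7B2
COX7C
COX8C
COX10
COX11
COX14
COX15
COX16
COX17
COX18
COX19
COX20
ATP5B
ATP5C1
ATP5D
ATP5E
ATP5G1
ATP5G2
ATP5H
ATP5I
ATP5J2
ATP5L
ATP5S
ATPAF1
ATPAF2
SURF1
SCO1
SCO2
TACO1
LRPPRC
NDUFAF1
NDUFAF2
NDUFAF3
NDUFAF4
FOXRED1
ACAD9
TMEM70
ATP5O
ATP12A
ATP6V1C2
LHPP
OXA1L
PPA1
COX4I1
COX5B
COX6B1
COX7A2
COX8A
BCS1L
UQCRC1
UQCRH
SDHA
SDHC
NDUFA1
NDUFA2
NDUFA5
NDUFA8
NDUFB2
NDUFB5
NDUFB8
NDUFC2
NDUFS3
NDUFS6
NDUFV1
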