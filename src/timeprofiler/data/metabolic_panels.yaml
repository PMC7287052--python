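# Metabolic gene panels: 24 glycolysis enzymes/transporters and 31 OXPHOS
# (respiratory-chain complex I-V) mitochondrial proteins.
glycolysis:
  - ALDOA
  - ALDOB
  - ALDOC
  - BPGM
  - ENO1
  - ENO2
  - ENO3
  - GALM
  - GCK
  - GPI
  - HK2
  - HK3
  - PFKL
  - PGAM2
  - PGK1
  - PGK2
  - PGM1
  - PGM2
  - PGM3
  - PKLR
  - TPI1
  - GLUT1
  - LDHA
  - LDHB
oxphos:
  - ATP12A
  - ATP5A1
  - ATP5F1
  - ATP5G3
  - ATP5J
  - ATP5O
  - ATP6V1C2
  - LHPP
  - OXA1L
  - PPA1
  - COX4I1
  - COX5B
  - COX6B1
  - COX7A2
  - COX8A
  - BCS1L
  - UQCRC1
  - UQCRH
  - SDHA
  - SDHC
  - NDUFA1
  - NDUFA2
  - NDUFA5
  - NDUFA8
  - NDUFB2
  - NDUFB5
  - NDUFB8
  - NDUFC2
  - NDUFS3
  - NDUFS6
  - NDUFV1
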