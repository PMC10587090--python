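gene	cluster
ANLN	1
BIRC5	1
CCNB1	1
CCNE1	1
CDC20	1
CDC6	1
CENPF	1
CEP55	1
EXO1	1
KIF2C	1
MELK	1
MKI67	1
MYBL2	1
NDC80	1
NUF2	1
ORC6	1
PTTG1	1
RRM2	1
TYMS	1
UBE2C	1
UBE2T	1
ESR1	2
FOXA1	2
PGR	2
BCL2	2
SLC39A6	2
MAPT	2
NAT1	2
MLPH	2
CXXC5	2
CDH3	3
KRT17	3
KRT5	3
KRT14	3
MIA	3
SFRP1	3
EGFR	3
FOXC1	3
ERBB2	4
GRB7	4
ACTR3B	5
PHGDH	5
GPR160	6
TMEM45B	6
FGFR4	7
MYC	NA
MMP11	NA
BAG1	NA
MDM2	NA
BLVRA	NA
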